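"""Clustering evaluation: NMI, the size-preserving null NMI*, and AMI.

NMI alone suffers from selection bias (it grows with the number of clusters),
so empirical scores are reported relative to NMI*, the mean NMI obtained by
reshuffling the predicted labels over the samples -- a null model that keeps
the number of clusters and their sizes but destroys any real association.
NMI/NMI* near 1 means the clustering is no better than chance.  AMI (adjusted
mutual information under the permutation model) is used to compare two
clusterings when neither is ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label arrays must be 1-D and of equal length")
    if len(a) == 0:
        raise ValueError("label arrays must be non-empty")
    return a, b


def contingency(a, b) -> np.ndarray:
    a, b = _check_pair(a, b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def entropy_nats(labels) -> float:
    """Shannon entropy of the label distribution, in nats."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(a, b) -> float:
    """Mutual information between two labelings, in nats."""
    nij = contingency(a, b).astype(float)
    n = nij.sum()
    pi = nij.sum(axis=1) / n
    pj = nij.sum(axis=0) / n
    pij = nij / n
    mask = pij > 0
    outer = pi[:, None] * pj[None, :]
    return float((pij[mask] * np.log(pij[mask] / outer[mask])).sum())


def nmi(labels_a, labels_b, average: str = "arithmetic") -> float:
    """Normalized mutual information in [0, 1].

    Normalization divides MI by the arithmetic mean of the two label
    entropies by default (``geometric``, ``min`` and ``max`` are available).
    By convention the score is 0 whenever either partition has a single
    cluster (zero entropy), which keeps the null score NMI* finite.
    """
    a, b = _check_pair(labels_a, labels_b)
    ha, hb = entropy_nats(a), entropy_nats(b)
    if ha == 0.0 or hb == 0.0:
        return 0.0
    mi = mutual_information(a, b)
    if average == "arithmetic":
        norm = (ha + hb) / 2
    elif average == "geometric":
        norm = float(np.sqrt(ha * hb))
    elif average == "min":
        norm = min(ha, hb)
    elif average == "max":
        norm = max(ha, hb)
    else:
        raise ValueError(f"unknown normalization: {average!r}")
    return float(np.clip(mi / norm, 0.0, 1.0))


def nmi_null(
    pred_labels,
    true_labels,
    n_shuffles: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_samples: bool = False,
):
    """NMI*: mean NMI of size-preserving random relabelings of ``pred``.

    Each shuffle permutes the predicted labels over the samples, preserving
    the number of clusters and their sizes by construction.
    """
    pred, true = _check_pair(pred_labels, true_labels)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = np.empty(n_shuffles)
    for i in range(n_shuffles):
        samples[i] = nmi(rng.permutation(pred), true)
    if return_samples:
        return float(samples.mean()), samples
    return float(samples.mean())


def ami(labels_a, labels_b, average: str = "arithmetic") -> float:
    """Adjusted mutual information under the permutation model.

    AMI = (MI - E[MI]) / (mean(H_a, H_b) - E[MI]), where the expectation runs
    over random contingency tables with the observed margins (hypergeometric
    model).  Identical partitions score 1; independent ones score ~0.
    """
    a, b = _check_pair(labels_a, labels_b)
    nij = contingency(a, b)
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    if len(ai) == 1 and len(bj) == 1:
        return 1.0
    ha, hb = entropy_nats(a), entropy_nats(b)
    if ha == 0.0 and hb == 0.0:
        return 1.0
    mi = mutual_information(a, b)
    emi = expected_mutual_information(ai, bj)
    if average == "arithmetic":
        norm = (ha + hb) / 2
    elif average == "geometric":
        norm = float(np.sqrt(ha * hb))
    elif average == "min":
        norm = min(ha, hb)
    elif average == "max":
        norm = max(ha, hb)
    else:
        raise ValueError(f"unknown normalization: {average!r}")
    denom = norm - emi
    if denom == 0.0:
        denom = np.finfo(float).eps
    return float((mi - emi) / denom)


def expected_mutual_information(ai: np.ndarray, bj: np.ndarray) -> float:
    """E[MI] over random tables with margins ``ai``, ``bj`` (permutation model).

    Direct evaluation of the exact sum: for every margin pair (a_i, b_j) the
    cell count n_ij follows a hypergeometric law; each admissible n_ij
    contributes n_ij/N * ln(N n_ij / (a_i b_j)) weighted by its probability.
    """
    ai = np.asarray(ai, dtype=np.int64)
    bj = np.asarray(bj, dtype=np.int64)
    N = int(ai.sum())
    lg = gammaln  # ln Gamma, vectorized
    emi = 0.0
    for a in ai:
        a = int(a)
        for b in bj:
            b = int(b)
            lo = max(1, a + b - N)
            hi = min(a, b)
            if hi < lo:
                continue
            k = np.arange(lo, hi + 1)
            term = (k / N) * (np.log(N * k) - np.log(a * b))
            logp = (
                lg(a + 1) - lg(k + 1) - lg(a - k + 1)
                + lg(N - a + 1) - lg(b - k + 1) - lg(N - a - b + k + 1)
                - (lg(N + 1) - lg(b + 1) - lg(N - b + 1))
            )
            emi += float((term * np.exp(logp)).sum())
    return emi


@dataclass
class ClusteringScore:
    """NMI of a clustering against labels, with its size-preserving null."""

    nmi: float
    nmi_star: float
    ratio: float
    n_shuffles: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "nmi": self.nmi,
            "nmi_star": self.nmi_star,
            "ratio": self.ratio,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
        }


def score_clustering(
    pred_labels, true_labels, n_shuffles: int = 100, seed: int | None = 0
) -> ClusteringScore:
    """Compute NMI, NMI* and their ratio for a clustering vs ground truth."""
    val = nmi(pred_labels, true_labels)
    star = nmi_null(pred_labels, true_labels, n_shuffles=n_shuffles, seed=seed)
    ratio = val / star if star > 0 else float("inf") if val > 0 else float("nan")
    return ClusteringScore(val, star, ratio, n_shuffles, seed)
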