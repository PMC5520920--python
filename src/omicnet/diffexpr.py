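"""Per-layer differential statistics and feature clustering.

One-way fixed-effects ANOVA per feature (vectorized sums of squares), row
z-scoring, hierarchical clustering of features with a random-substitution
specificity score, and signature overlap counting against the tested
universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from omicnet.io import Signature, canonical_symbol
from omicnet.modstats import hypergeom_overlap

log = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.05, 0.01)


@dataclass
class DEResult:
    """Per-feature differential record for one omic layer."""

    symbol: str
    layer: str
    group_means: tuple[float, ...]
    f_stat: float
    p_value: float
    direction: int  # +1 / -1, sign of (second group mean - first)
    significant_at: dict[float, bool] = field(default_factory=dict)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalize each row to mean 0 and unit sample (n-1) variance.

    Constant rows cannot be scaled and are dropped with a logged count.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples per row")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("zscore_rows: dropped %d constant row(s)", dropped)
    values = values[keep]
    out = (values - values.mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(out, index=matrix.index[keep], columns=matrix.columns)


def anova_de(
    matrix: pd.DataFrame,
    groups: list[str],
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    layer: str = "transcript",
) -> list[DEResult]:
    """One-way ANOVA per feature (rows) across sample groups (columns).

    In the two-group case F equals the squared pooled-variance t statistic.
    Features that are constant within every group get F=0, p=1.
    """
    labels = list(dict.fromkeys(groups))  # first-appearance order
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(groups) != matrix.shape[1]:
        raise ValueError("one group label per sample column required")
    idx = {g: [i for i, x in enumerate(groups) if x == g] for g in labels}
    if any(len(v) < 2 for v in idx.values()):
        raise ValueError("need at least two samples per group")

    x = matrix.to_numpy(dtype=float)
    n_total = x.shape[1]
    k = len(labels)
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    means = {}
    for g in labels:
        xg = x[:, idx[g]]
        mg = xg.mean(axis=1)
        means[g] = mg
        ssb += len(idx[g]) * (mg - grand) ** 2
        ssw += ((xg - mg[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    f = np.where(ssw > 0, f, np.where(ssb > 0, np.inf, 0.0))
    p = st.f.sf(f, dfb, dfw)
    p = np.where(np.isinf(f), 0.0, np.where(f == 0.0, 1.0, p))

    diff = means[labels[1]] - means[labels[0]]
    direction = np.where(diff >= 0, 1, -1)
    return [
        DEResult(
            symbol=canonical_symbol(sym),
            layer=layer,
            group_means=tuple(float(means[g][i]) for g in labels),
            f_stat=float(f[i]),
            p_value=float(p[i]),
            direction=int(direction[i]),
            significant_at={a: bool(p[i] < a) for a in alphas},
        )
        for i, sym in enumerate(matrix.index)
    ]


def hcluster(
    matrix: pd.DataFrame,
    n_clusters: int,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster features (rows) hierarchically; returns (labels, linkage).

    Euclidean distance with average linkage by default; deterministic for a
    fixed matrix, and invariant to feature order up to label renumbering.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > matrix.shape[0]:
        raise ValueError("n_clusters exceeds number of features")
    if matrix.shape[0] == 1:
        return np.array([1]), np.empty((0, 4))
    z = sch.linkage(matrix.to_numpy(dtype=float), method=method, metric=metric)
    labels = sch.fcluster(z, t=n_clusters, criterion="maxclust")
    return labels, z


def _best_jaccard(original: set, partition: dict[int, set]) -> float:
    return max(
        (len(original & m) / len(original | m) for m in partition.values()),
        default=0.0,
    )


def cluster_specificity(
    matrix: pd.DataFrame,
    clusters: np.ndarray,
    n_iter: int = 10,
    substitution_fraction: float = 0.1,
    seed: int = 0,
    **hcluster_kwargs,
) -> dict[int, float]:
    """Random-substitution stability of a feature clustering.

    Each iteration replaces a fraction of feature rows with rows drawn at
    random from the full matrix, re-clusters, and records each original
    cluster's best Jaccard similarity to the new partition; the score is the
    mean over iterations.
    """
    if not 0 < substitution_fraction < 1:
        raise ValueError("substitution_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = matrix.shape[0]
    n_clusters = len(np.unique(clusters))
    originals = {c: set(np.flatnonzero(clusters == c)) for c in np.unique(clusters)}
    n_sub = int(round(substitution_fraction * n))
    scores = {c: [] for c in originals}
    for _ in range(n_iter):
        perturbed = matrix.to_numpy(dtype=float).copy()
        if n_sub:
            targets = rng.choice(n, size=n_sub, replace=False)
            sources = rng.choice(n, size=n_sub, replace=True)
            perturbed[targets] = matrix.to_numpy(dtype=float)[sources]
        new_labels, _ = hcluster(
            pd.DataFrame(perturbed, index=matrix.index, columns=matrix.columns),
            n_clusters,
            **hcluster_kwargs,
        )
        new_parts = {c: set(np.flatnonzero(new_labels == c)) for c in np.unique(new_labels)}
        for c, members in originals.items():
            scores[c].append(_best_jaccard(members, new_parts))
    return {int(c): float(np.mean(v)) for c, v in scores.items()}


def signature_overlap(
    de: list[DEResult], signature: Signature, alpha: float
) -> tuple[int, int, float]:
    """Count signature members among tested and significant features.

    Returns (n signature members tested, n of them significant at ``alpha``,
    upper-tail hypergeometric p with the tested features as universe).
    """
    tested = {r.symbol for r in de}
    sig_members = set(signature.members) & tested
    if not sig_members:
        raise ValueError(
            f"signature {signature.name!r} shares no members with tested features"
        )
    significant = {r.symbol for r in de if r.p_value < alpha}
    overlap = sig_members & significant
    p = hypergeom_overlap(
        n_a=len(sig_members),
        n_b=len(significant),
        k_overlap=len(overlap),
        universe=len(tested),
    )
    return len(sig_members), len(overlap), p
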