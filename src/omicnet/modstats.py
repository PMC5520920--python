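"""Exact-test machinery for module statistics.

Fisher's exact test computed with exact rational arithmetic, Woolf logit
confidence intervals with a Haldane–Anscombe zero-cell rule, upper-tail
hypergeometric overlap probabilities, Benjamini–Hochberg correction, module
connectivity enrichment against a background interactome, and cross-dataset
module-set comparison.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    module: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None
    zero_cell_corrected: bool = False


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    universe: int
    overlap: int
    p_value: float
    matched_pairs: tuple[tuple[str, str], ...] = ()


def _validate_table(table) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("2x2 table must hold non-negative integers")
    return tuple(int(x) for x in cells)


def odds_ratio(table) -> tuple[float, bool]:
    """Sample odds ratio; Haldane–Anscombe +0.5 applied only on a zero cell.

    Returns (OR, corrected?).
    """
    a, b, c, d = _validate_table(table)
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def woolf_ci(table, z: float = 1.959963984540054) -> tuple[float, float]:
    """Woolf logit 95% CI, on the zero-cell-corrected table when needed."""
    a, b, c, d = _validate_table(table)
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_ * math.exp(-z * se), or_ * math.exp(z * se)


def _hypergeom_pmf_exact(r1: int, r2: int, c1: int) -> dict[int, Fraction]:
    n = r1 + r2
    denom = math.comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    return {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(kmin, kmax + 1)
    }


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    p is the sum of probabilities, over all tables with the observed margins,
    whose point probability is <= the observed table's (computed exactly with
    rational arithmetic, so ties are exact). Returns (p, sample odds ratio
    with the zero-cell rule). Raises on a zero margin.
    """
    a, b, c, d = _validate_table(table)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("2x2 table has a zero margin")
    pmf = _hypergeom_pmf_exact(r1, r2, c1)
    p_obs = pmf[a]
    p = sum(q for q in pmf.values() if q <= p_obs)
    or_, _ = odds_ratio(((a, b), (c, d)))
    return float(p), or_


def _fisher_or_degenerate(table) -> float:
    """Fisher p, defining a zero-margin table (single possible table) as p=1."""
    a, b, c, d = _validate_table(table)
    if 0 in (a + b, c + d, a + c, b + d):
        return 1.0
    return fisher_exact(table)[0]


def hypergeom_overlap(n_a: int, n_b: int, k_overlap: int, universe: int) -> float:
    """Exact upper-tail overlap probability P[X >= k] for |A|=n_a, |B|=n_b

    drawn from a universe of the given size.
    """
    if not (0 <= k_overlap <= min(n_a, n_b) <= universe and max(n_a, n_b) <= universe):
        raise ValueError(
            f"invalid overlap arguments n_a={n_a} n_b={n_b} k={k_overlap} N={universe}"
        )
    denom = math.comb(universe, n_b)
    total = Fraction(0)
    for j in range(k_overlap, min(n_a, n_b) + 1):
        if n_b - j > universe - n_a:
            continue
        total += Fraction(math.comb(n_a, j) * math.comb(universe - n_a, n_b - j), denom)
    return float(total)


def bh_correct(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, invariant to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def connectivity_enrichment(
    module_members: dict[str, set[str]],
    study_network,
    background,
) -> list[EnrichmentResult]:
    """Edge-density enrichment of each module versus a background interactome.

    For each module the 2x2 table counts {edges, non-edges} among the module's
    member pairs in the study network (row 1) and in the background graph
    restricted to the same pairs (row 2). Modules with fewer than two members
    are skipped with a log message; members missing from the background node
    set raise.
    """
    import networkx as nx  # local import to keep scipy-only callers light

    study_g = study_network if isinstance(study_network, nx.Graph) else study_network.graph
    bg_g = background if isinstance(background, nx.Graph) else background.graph

    results = []
    for label, members in module_members.items():
        missing = set(members) - set(bg_g.nodes)
        if missing:
            raise KeyError(
                f"module {label!r}: members absent from background: {sorted(missing)[:5]}"
            )
        if len(members) < 2:
            log.info("module %r has <2 members; skipped", label)
            continue
        pairs = list(itertools.combinations(sorted(members), 2))
        a = sum(1 for u, v in pairs if study_g.has_edge(u, v))
        c = sum(1 for u, v in pairs if bg_g.has_edge(u, v))
        n_pairs = len(pairs)
        table = ((a, n_pairs - a), (c, n_pairs - c))
        or_, corrected = odds_ratio(table)
        lo, hi = woolf_ci(table)
        p = _fisher_or_degenerate(table)
        results.append(
            EnrichmentResult(
                module=label,
                table=table,
                odds_ratio=or_,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                zero_cell_corrected=corrected,
            )
        )
    if results:
        q = bh_correct([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def compare_module_sets(
    cores_a,
    cores_b,
    universe,
    members_a: dict[str, set[str]] | None = None,
    members_b: dict[str, set[str]] | None = None,
    matching_rule: str = "core",
    jaccard_threshold: float = 0.5,
) -> OverlapResult:
    """Overlap of two module inventories labeled by core symbols.

    ``matching_rule="core"`` matches modules sharing a core symbol (the
    default); ``"jaccard"`` greedily matches modules whose member Jaccard
    similarity reaches ``jaccard_threshold`` (requires member dicts). p comes
    from :func:`hypergeom_overlap` over the symbols eligible to be cores in
    both analyses.
    """
    cores_a, cores_b = set(cores_a), set(cores_b)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if matching_rule == "core":
        matched = tuple((s, s) for s in sorted(cores_a & cores_b))
    elif matching_rule == "jaccard":
        if members_a is None or members_b is None:
            raise ValueError("jaccard matching needs member sets")
        pairs = sorted(
            (
                (len(ma & mb) / len(ma | mb), la, lb)
                for la, ma in members_a.items()
                for lb, mb in members_b.items()
                if ma | mb
            ),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_a, used_b, matched = set(), set(), []
        for j, la, lb in pairs:
            if j < jaccard_threshold:
                break
            if la in used_a or lb in used_b:
                continue
            used_a.add(la)
            used_b.add(lb)
            matched.append((la, lb))
        matched = tuple(matched)
    else:
        raise ValueError(f"unknown matching rule {matching_rule!r}")
    p = hypergeom_overlap(
        n_a=len(cores_a), n_b=len(cores_b), k_overlap=len(matched), universe=len(universe)
    )
    return OverlapResult(
        n_a=len(cores_a),
        n_b=len(cores_b),
        universe=len(universe),
        overlap=len(matched),
        p_value=p,
        matched_pairs=matched,
    )
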