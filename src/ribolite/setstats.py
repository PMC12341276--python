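"""Gene-set overlap and rank statistics.

Overlap fold enrichment with an upper-tail hypergeometric p-value, the
Mann-Whitney U rank test (exact for small tie-free samples, otherwise the
normal approximation with tie and continuity corrections), and a generic
annotation-driven term-enrichment operation (per-term one-sided Fisher exact
test with Benjamini-Hochberg correction across terms) that works against any
user-supplied term -> gene mapping.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .difftrans import bh_adjust

EXACT_MW_MAX_PRODUCT = 64


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets within a universe."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    fold_enrichment: float
    p_hypergeometric: float


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney U test result (U reported for the first sample)."""

    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    tie_corrected: bool
    exact: bool
    degenerate: bool = False


def overlap_enrichment(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Fold enrichment (observed/expected overlap rate) and the upper-tail
    hypergeometric probability of an overlap at least as large."""
    a, b, u = set(set_a), set(set_b), set(universe)
    offenders = sorted((a | b) - u)
    if offenders:
        raise ValueError(f"gene sets not contained in universe: {offenders[:10]}")
    if not a or not b or not u:
        raise ValueError("set_a, set_b and universe must be non-empty")
    overlap = len(a & b)
    fold = (overlap / len(a)) / (len(b) / len(u))
    p = float(stats.hypergeom.sf(overlap - 1, len(u), len(b), len(a)))
    return OverlapResult(
        set_a_size=len(a),
        set_b_size=len(b),
        universe_size=len(u),
        overlap=overlap,
        fold_enrichment=fold,
        p_hypergeometric=p,
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U rank test.

    Uses the exact null distribution when n1*n2 <= 64 and the data are
    tie-free; otherwise the normal approximation with midrank tie correction
    and continuity correction. Two identical constant samples are degenerate
    and reported with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if np.ptp(pooled) == 0:
        return RankTestResult(
            u_statistic=n1 * n2 / 2.0,
            p_two_sided=1.0,
            n1=n1,
            n2=n2,
            tie_corrected=True,
            exact=False,
            degenerate=True,
        )
    exact = (n1 * n2 <= EXACT_MW_MAX_PRODUCT) and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_two_sided=float(np.clip(res.pvalue, np.finfo(float).tiny, 1.0)),
        n1=n1,
        n2=n2,
        tie_corrected=has_ties,
        exact=exact,
    )


def term_enrichment(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-term overlap enrichment of a query gene set against an annotation.

    For each term a 2x2 table (query membership x term membership over the
    universe) is tested with the one-sided Fisher exact test (equivalently
    the hypergeometric upper tail); p-values are BH-adjusted across terms.
    """
    q = set(query)
    u = set(universe)
    if not annotation:
        raise ValueError("annotation must be non-empty")
    if not q:
        raise ValueError("query gene set is empty")
    offenders = sorted(q - u)
    if offenders:
        raise ValueError(f"query genes outside universe: {offenders[:10]}")
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & u
        overlap = len(q & term_genes)
        expected_rate = len(term_genes) / len(u) if term_genes else 0.0
        fold = (overlap / len(q)) / expected_rate if expected_rate > 0 else float("nan")
        if term_genes:
            table = [
                [overlap, len(q) - overlap],
                [len(term_genes) - overlap, len(u) - len(q) - len(term_genes) + overlap],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
        else:
            p = 1.0
        rows.append(
            {
                "term": term,
                "term_size": len(term_genes),
                "overlap": overlap,
                "fold_enrichment": fold,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
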