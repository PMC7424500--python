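"""Differential expression: fold-change filter ∩ BH-controlled Welch tests.

A gene is called differentially expressed at a week when (a) the absolute
difference of its group mean log2 values strictly exceeds the fold-change
threshold (default 1, i.e. strictly more than two-fold on the original
scale) and (b) its two-tailed Welch t-test is rejected by the
Benjamini–Hochberg step-up rule at E(FDR) <= alpha across all genes tested
at that week.  Gene-set overlap significance uses the one-tailed
(over-representation) Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, GeneSet, SampleMetadata

__all__ = [
    "welch_t",
    "bh_reject",
    "extract_degs",
    "union_degs",
    "overlap_stats",
    "OverlapResult",
]


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Two-sample Welch t-test.

    Returns ``(t, df, p)`` with the unequal-variance statistic, the
    Welch–Satterthwaite degrees of freedom and the two-tailed p-value.
    Degenerate convention when both sample variances are zero: equal means
    give ``t = 0, p = 1``; unequal means give ``p = 0`` with t of the
    appropriate infinite sign.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(diff)) * float("inf"), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_reject(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level ``alpha``.

    Sort p ascending, find the largest k with p_(k) <= k*alpha/m and
    reject hypotheses 1..k; equal p-values necessarily share a decision.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(p[order] <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1] + 1
        reject[order[:k]] = True
    return reject


def _welch_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test for genes x samples blocks (same conventions as welch_t)."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    se2 = va / na + vb / nb
    t = np.zeros_like(diff)
    df = np.full_like(diff, float(na + nb - 2))
    p = np.ones_like(diff)
    ok = se2 > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t[ok] = diff[ok] / np.sqrt(se2[ok])
        df[ok] = se2[ok] ** 2 / (
            (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
        )
        p[ok] = np.minimum(2.0 * stats.t.sf(np.abs(t[ok]), df[ok]), 1.0)
    degenerate = ~ok & (diff != 0)
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p[degenerate] = 0.0
    return t, df, p


def extract_degs(
    log2_matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    week: int,
    alpha: float = 0.05,
    fc_log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DEG table for one week (control vs treated).

    Columns: gene, mean_log2_control, mean_log2_treated, delta, t, df, p,
    bh_reject, fc_candidate, is_deg.  ``delta`` is treated minus control;
    the fold-change flag requires ``|delta|`` strictly greater than the
    threshold; the final flag is the intersection with the BH rejection.
    """
    cells = {}
    for group in ("control", "treated"):
        ids = metadata.samples_in_cell(group, week)
        if len(ids) < 2:
            raise ValueError(
                f"cell ({group}, week {week}) has {len(ids)} samples; need >= 2"
            )
        cells[group] = log2_matrix.data.loc[:, ids].to_numpy(dtype=float)

    t, df, p = _welch_vectorized(cells["treated"], cells["control"])
    mean_c = cells["control"].mean(axis=1)
    mean_t = cells["treated"].mean(axis=1)
    delta = mean_t - mean_c
    fc = np.abs(delta) > fc_log2_threshold
    bh = bh_reject(p, alpha=alpha)
    return pd.DataFrame(
        {
            "gene": log2_matrix.genes,
            "mean_log2_control": mean_c,
            "mean_log2_treated": mean_t,
            "delta": delta,
            "t": t,
            "df": df,
            "p": p,
            "bh_reject": bh,
            "fc_candidate": fc,
            "is_deg": fc & bh,
        }
    ).set_index("gene", drop=False)


def union_degs(tables: dict[int, pd.DataFrame] | list[pd.DataFrame]) -> GeneSet:
    """Union of the final DEG calls across per-week tables."""
    if isinstance(tables, dict):
        items = [tables[k] for k in sorted(tables)]
    else:
        items = list(tables)
    if not items:
        raise ValueError("need at least one DEG table")
    genes: list[str] = []
    for table in items:
        genes.extend(table.loc[table["is_deg"], "gene"].tolist())
    return GeneSet(sorted(set(genes)), name="deg_union")


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric/Fisher summary of the overlap of two gene sets."""

    universe_size: int
    size_a: int
    size_b: int
    observed: int
    expected: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "N": self.universe_size,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "observed": self.observed,
            "expected": self.expected,
            "p_value": self.p_value,
        }


def overlap_stats(
    set_a: GeneSet,
    set_b: GeneSet,
    universe_size: int,
    observed: int | None = None,
) -> OverlapResult:
    """Chance-level expectation and one-tailed Fisher p for a set overlap.

    Expected overlap is ``|A|*|B|/N``; the p-value is the hypergeometric
    upper tail ``P[X >= observed]`` (over-representation).  ``observed``
    defaults to the actual intersection size but may be supplied directly
    when only the set sizes are known.
    """
    ka, kb = len(set_a), len(set_b)
    if ka > universe_size or kb > universe_size:
        raise ValueError("set sizes exceed universe size")
    if observed is None:
        observed = len(set_a.as_set() & set_b.as_set())
    if observed > min(ka, kb):
        raise ValueError("observed overlap exceeds the smaller set")
    expected = ka * kb / universe_size if universe_size else 0.0
    p = float(stats.hypergeom.sf(observed - 1, universe_size, ka, kb))
    return OverlapResult(
        universe_size=universe_size,
        size_a=ka,
        size_b=kb,
        observed=int(observed),
        expected=float(expected),
        p_value=min(p, 1.0),
    )
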