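"""Early-warning scores over a designated gene set, per (group, week) cell.

Two statistics are computed from the log2 expression of the gene set S
within one cell of n samples:

* ``I_s`` — the mean of the per-gene sample standard deviations s_i
  (n-1 denominator).
* ``I_r`` — the mean over unordered gene pairs of ``|r_ij| - c(n)``, where
  r_ij is the Pearson correlation across the cell's samples and c(n) is
  the expected absolute sample correlation of two independent standard
  normal variables at sample size n.  The correction makes the null
  expectation of each pair contribution exactly zero, so I_r hovers near 0
  for independent genes and rises when the set co-fluctuates.

"Correlation strength" is the absolute correlation: the correction term is
defined as an expected *strength* (nonnegative), which matches E|r| and
not E[r] = 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .data import ExpressionMatrix, GeneSet, SampleMetadata

__all__ = [
    "correction_term",
    "correction_term_mc",
    "average_sd",
    "average_correlation_strength",
    "score_timecourse",
    "suppression_summary",
    "DNBScoreSeries",
    "SuppressionSummary",
]

logger = logging.getLogger(__name__)


def correction_term(n: int) -> float:
    """Expected absolute sample correlation of two independent normals.

    Closed form ``E|r| = 2 / ((n - 2) * B(1/2, (n - 2)/2))`` for n >= 3
    paired samples; evaluates to 2/pi, 1/2 and 4/(3*pi) at n = 3, 4, 5
    (0.64, 0.50, 0.42 to two decimals).  Strictly decreasing in n, -> 0.
    """
    if int(n) != n or n < 3:
        raise ValueError("correction term requires an integer sample size n >= 3")
    n = int(n)
    return float(2.0 / ((n - 2) * special.beta(0.5, (n - 2) / 2.0)))


def correction_term_mc(n: int, n_replicates: int = 1_000_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo cross-check of :func:`correction_term`.

    Simulates ``n_replicates`` pairs of independent standard-normal samples
    of size n and returns (mean |r|, standard error of the mean).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    abs_r = np.empty(n_replicates)
    chunk = 50_000
    done = 0
    while done < n_replicates:
        size = min(chunk, n_replicates - done)
        x = rng.standard_normal((size, n))
        y = rng.standard_normal((size, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        abs_r[done : done + size] = np.abs(num / den)
        done += size
    return float(abs_r.mean()), float(abs_r.std(ddof=1) / np.sqrt(n_replicates))


def _cell_block(
    log2_matrix: ExpressionMatrix,
    gene_set: GeneSet,
    group: str,
    week: int,
    metadata: SampleMetadata,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Values of the set's genes over one cell; returns (block, genes, samples)."""
    ids = metadata.samples_in_cell(group, week)
    present = [g for g in gene_set if g in log2_matrix.data.index]
    missing = [g for g in gene_set if g not in log2_matrix.data.index]
    if missing:
        logger.warning(
            "MISSING_DNB_GENES\tcell=%s:w%d\tcount=%d\tgenes=%s",
            group, week, len(missing), ",".join(missing[:20]),
        )
    block = log2_matrix.data.loc[present, ids].to_numpy(dtype=float)
    return block, present, ids


def average_sd(
    log2_matrix: ExpressionMatrix,
    gene_set: GeneSet,
    group: str,
    week: int,
    metadata: SampleMetadata,
) -> tuple[float, pd.Series]:
    """Average standard deviation I_s and the per-gene SDs for one cell."""
    block, present, ids = _cell_block(log2_matrix, gene_set, group, week, metadata)
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    if len(ids) < 2:
        raise ValueError(f"cell ({group}, week {week}) has {len(ids)} samples; need >= 2")
    sds = pd.Series(block.std(axis=1, ddof=1), index=pd.Index(present, name="gene"))
    return float(sds.mean()), sds


def average_correlation_strength(
    log2_matrix: ExpressionMatrix,
    gene_set: GeneSet,
    group: str,
    week: int,
    metadata: SampleMetadata,
) -> float:
    """Corrected average correlation strength I_r for one cell.

    Mean over unordered pairs of ``|r_ij| - c(n)``; constant genes are
    excluded with a warning.  May be (slightly) negative under the null.
    """
    block, present, ids = _cell_block(log2_matrix, gene_set, group, week, metadata)
    n = len(ids)
    if n < 3:
        raise ValueError(f"cell ({group}, week {week}) has {n} samples; need >= 3")
    sds = block.std(axis=1, ddof=1)
    if (sds == 0).any():
        dropped = [g for g, s in zip(present, sds) if s == 0]
        logger.warning(
            "CONSTANT_GENES\tcell=%s:w%d\tcount=%d\tgenes=%s",
            group, week, len(dropped), ",".join(dropped[:20]),
        )
        block = block[sds > 0]
        present = [g for g, s in zip(present, sds) if s > 0]
    if len(present) < 2:
        raise ValueError("fewer than 2 usable (non-constant) genes in the cell")
    r = np.corrcoef(block)
    iu = np.triu_indices(len(present), k=1)
    strengths = np.abs(np.clip(r[iu], -1.0, 1.0))
    return float((strengths - correction_term(n)).mean())


@dataclass
class DNBScoreSeries:
    """Scores per (group, week) cell plus per-gene SD detail.

    ``table`` columns: group, week, n_samples, n_genes, c, I_s, I_r (I_r is
    NaN for cells with fewer than 3 samples, which are reported, not
    dropped).  ``per_gene_sd`` columns: gene, group, week, sd.
    """

    table: pd.DataFrame
    per_gene_sd: pd.DataFrame
    missing_cells: list[tuple[str, int, str]] = field(default_factory=list)

    def cell(self, group: str, week: int) -> pd.Series:
        mask = (self.table["group"] == group) & (self.table["week"] == week)
        sub = self.table.loc[mask]
        if sub.empty:
            raise KeyError(f"no scored cell ({group}, week {week})")
        return sub.iloc[0]

    def sds_for(self, group: str, week: int) -> pd.Series:
        mask = (self.per_gene_sd["group"] == group) & (self.per_gene_sd["week"] == week)
        sub = self.per_gene_sd.loc[mask]
        return pd.Series(sub["sd"].to_numpy(), index=pd.Index(sub["gene"], name="gene"))


def score_timecourse(
    log2_matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    gene_set: GeneSet,
) -> DNBScoreSeries:
    """I_s and I_r for every (group, week) cell with sufficient samples.

    Cells with fewer than 2 samples are skipped and recorded in
    ``missing_cells``; cells with exactly 2 get I_s but no I_r.
    """
    rows = []
    sd_rows = []
    missing: list[tuple[str, int, str]] = []
    for group, week, ids in metadata.cells():
        n = len(ids)
        if n < 2:
            missing.append((group, week, f"only {n} sample(s)"))
            continue
        i_s, sds = average_sd(log2_matrix, gene_set, group, week, metadata)
        for gene, sd in sds.items():
            sd_rows.append((gene, group, week, sd))
        if n >= 3:
            c = correction_term(n)
            i_r = average_correlation_strength(log2_matrix, gene_set, group, week, metadata)
        else:
            c, i_r = np.nan, np.nan
            missing.append((group, week, "n < 3: I_r undefined"))
        rows.append((group, week, n, len(sds), c, i_s, i_r))
    if not rows:
        raise ValueError("no scorable (group, week) cell in the metadata")
    table = pd.DataFrame(
        rows, columns=["group", "week", "n_samples", "n_genes", "c", "I_s", "I_r"]
    )
    per_gene = pd.DataFrame(sd_rows, columns=["gene", "group", "week", "sd"])
    return DNBScoreSeries(table=table, per_gene_sd=per_gene, missing_cells=missing)


@dataclass(frozen=True)
class SuppressionSummary:
    """Treated-vs-control comparison of the score components at one week."""

    week: int
    n_genes: int
    n_decreased: int
    n_halved: int
    is_ratio_pct: float
    ir_ratio_pct: float

    def to_dict(self) -> dict:
        return {
            "week": self.week,
            "n_genes": self.n_genes,
            "n_decreased": self.n_decreased,
            "n_halved": self.n_halved,
            "Is_ratio_pct": self.is_ratio_pct,
            "Ir_ratio_pct": self.ir_ratio_pct,
        }


def suppression_summary(
    scores_control: DNBScoreSeries,
    scores_treated: DNBScoreSeries,
    week: int,
) -> SuppressionSummary:
    """Count per-gene SD reductions and score ratios at one week.

    ``n_decreased`` counts genes with treated SD strictly below control SD;
    ``n_halved`` those strictly below half of it.  Ratios are
    treated/control in percent.
    """
    sd_c = scores_control.sds_for("control", week)
    sd_t = scores_treated.sds_for("treated", week)
    if set(sd_c.index) != set(sd_t.index):
        diff = sorted(set(sd_c.index) ^ set(sd_t.index))
        raise ValueError(f"gene sets differ between groups: {diff[:20]}")
    sd_t = sd_t.reindex(sd_c.index)
    n_decreased = int((sd_t < sd_c).sum())
    n_halved = int((sd_t < 0.5 * sd_c).sum())
    cell_c = scores_control.cell("control", week)
    cell_t = scores_treated.cell("treated", week)
    is_ratio = 100.0 * cell_t["I_s"] / cell_c["I_s"]
    ir_ratio = 100.0 * cell_t["I_r"] / cell_c["I_r"]
    return SuppressionSummary(
        week=int(week),
        n_genes=len(sd_c),
        n_decreased=n_decreased,
        n_halved=n_halved,
        is_ratio_pct=float(is_ratio),
        ir_ratio_pct=float(ir_ratio),
    )
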