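"""Synthetic time-course expression data with a planted early-warning spike.

The generator produces a two-group (control/treated), multi-week dataset in
which a designated gene set shares a per-sample latent factor at one
"spike" week of the control group.  That single device simultaneously
elevates per-gene standard deviations (Var = a**2 * kappa**2 + sigma**2)
and pairwise correlations (corr = a**2 * kappa**2 / (a**2 * kappa**2 + sigma**2)),
which is exactly the signal the downstream scores are designed to detect.
A second, disjoint gene set receives a between-group mean shift from a
configurable onset week, giving the fold-change/Welch stage a planted truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSet, SampleMetadata, SCALE_LOG2, SCALE_RAW

__all__ = ["SynthConfig", "LabeledDataset", "generate_dataset", "write_fixture"]


def _default_samples_per_cell() -> dict[tuple[str, int], int]:
    # control 5,5,5,4,5 over weeks 3..7; treated 3,4,4,4 over weeks 4..7
    cells = {("control", w): n for w, n in zip(range(3, 8), (5, 5, 5, 4, 5))}
    cells.update({("treated", w): n for w, n in zip(range(4, 8), (3, 4, 4, 4))})
    return cells


@dataclass
class SynthConfig:
    """All generator knobs; every field has a sensible default.

    ``dnb_loading`` is the latent-factor loading *a* (log2 units) applied to
    the planted gene set at ``spike_week``; ``treated_attenuation`` is the
    multiplier kappa in [0, 1] applied to that loading in the treated group
    (0 = fully suppressed).  ``deg_shift`` is the log2 mean shift added to
    planted DEGs in the treated group from ``deg_onset_week`` on.
    """

    n_genes: int = 3000
    n_dnb: int = 147
    n_deg: int = 100
    weeks: tuple[int, ...] = (3, 4, 5, 6, 7)
    samples_per_cell: Mapping[tuple[str, int], int] = field(
        default_factory=_default_samples_per_cell
    )
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.5
    dnb_loading: float = 1.0
    spike_week: int = 5
    treated_attenuation: float = 0.0
    deg_shift: float = 1.2
    deg_onset_week: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_dnb < 0:
            raise ValueError("n_dnb must be >= 0")
        if self.n_deg < 0:
            raise ValueError("n_deg must be >= 0")
        if self.n_dnb + self.n_deg > self.n_genes:
            raise ValueError("n_dnb + n_deg must not exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.treated_attenuation <= 1.0):
            raise ValueError("treated_attenuation must be in [0, 1]")
        if self.spike_week not in self.weeks:
            raise ValueError("spike_week must be one of weeks")
        if self.deg_onset_week not in self.weeks:
            raise ValueError("deg_onset_week must be one of weeks")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ValueError("baseline_mean_range must be a nonempty interval")
        for (group, week), n in self.samples_per_cell.items():
            if n < 0:
                raise ValueError(f"samples_per_cell[{(group, week)}] must be >= 0")
            if week not in self.weeks:
                raise ValueError(f"samples_per_cell week {week} not in weeks")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["samples_per_cell"] = {f"{g}:{w}": n for (g, w), n in self.samples_per_cell.items()}
        d["weeks"] = list(self.weeks)
        d["baseline_mean_range"] = list(self.baseline_mean_range)
        return d


@dataclass
class LabeledDataset:
    """A generated dataset together with its planted ground truth."""

    expression: ExpressionMatrix  # log2 scale
    metadata: SampleMetadata
    dnb_genes: GeneSet
    deg_genes: GeneSet
    config: SynthConfig

    def raw_expression(self) -> ExpressionMatrix:
        """Raw-intensity rendering: 2**x of every log2 value."""
        return ExpressionMatrix(np.exp2(self.expression.data), scale=SCALE_RAW)


def generate_dataset(config: SynthConfig) -> LabeledDataset:
    """Draw a labeled dataset from the one-factor planted model.

    For gene g and sample s in cell (group, week)::

        x = mu_g + a * kappa(group) * [g in DNB][week == spike] * z_s
                 + delta * [g in DEG][week >= onset][group == treated]
                 + eps,   eps ~ N(0, sigma^2)

    where ``z_s`` is a per-sample standard-normal factor shared by all
    planted DNB genes.  The same seed always yields a bit-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    dnb = genes[: config.n_dnb]
    deg = genes[config.n_dnb : config.n_dnb + config.n_deg]
    dnb_mask = np.zeros(config.n_genes, dtype=bool)
    dnb_mask[: config.n_dnb] = True
    deg_mask = np.zeros(config.n_genes, dtype=bool)
    deg_mask[config.n_dnb : config.n_dnb + config.n_deg] = True

    lo, hi = config.baseline_mean_range
    baselines = rng.uniform(lo, hi, size=config.n_genes)

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[tuple[str, str, int]] = []
    for group in ("control", "treated"):
        kappa = 1.0 if group == "control" else config.treated_attenuation
        for week in config.weeks:
            n = int(config.samples_per_cell.get((group, week), 0))
            for rep in range(n):
                sid = f"{group}_w{week}_r{rep + 1}"
                x = baselines + rng.normal(0.0, config.noise_sd, size=config.n_genes)
                if week == config.spike_week and config.n_dnb > 0:
                    z = rng.standard_normal()
                    x = x + config.dnb_loading * kappa * z * dnb_mask
                if group == "treated" and week >= config.deg_onset_week and config.n_deg > 0:
                    x = x + config.deg_shift * deg_mask
                columns.append(x)
                sample_ids.append(sid)
                meta_rows.append((sid, group, week))

    data = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((config.n_genes, 0)),
        index=pd.Index(genes, name="gene"),
        columns=sample_ids,
    )
    expression = ExpressionMatrix(data, scale=SCALE_LOG2)
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "group", "week"])
    )
    return LabeledDataset(
        expression=expression,
        metadata=metadata,
        dnb_genes=GeneSet(dnb, name="planted_dnb"),
        deg_genes=GeneSet(deg, name="planted_deg"),
        config=config,
    )


def write_fixture(dataset: LabeledDataset, directory: str | os.PathLike) -> dict[str, str]:
    """Write the dataset in the exact file dialects the CLI consumes.

    Returns a mapping of artifact name to path.  A raw-intensity rendering
    (2**x) is written alongside the log2 matrix so the preprocessing stage
    can be exercised end-to-end.
    """
    from . import io as dio

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression_log2": os.path.join(directory, "expression_log2.tsv"),
        "expression_raw": os.path.join(directory, "expression_raw.tsv"),
        "metadata": os.path.join(directory, "metadata.tsv"),
        "dnb_genes": os.path.join(directory, "dnb_genes.txt"),
        "deg_genes": os.path.join(directory, "planted_deg_genes.txt"),
    }
    dio.write_expression(dataset.expression, paths["expression_log2"])
    dio.write_expression(dataset.raw_expression(), paths["expression_raw"])
    dio.write_metadata(dataset.metadata, paths["metadata"])
    dio.write_geneset(dataset.dnb_genes, paths["dnb_genes"])
    dio.write_geneset(dataset.deg_genes, paths["deg_genes"])
    return paths
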