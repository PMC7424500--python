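"""Probe collapse, per-sample trimmed-mean normalization and log2 transform.

Order of operations is fixed: collapse probes on raw intensities, divide
each sample by its own 2% trimmed mean, then take log2.  Nonpositive
values are a hard error at every stage — no pseudo-counts.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, SCALE_LOG2, SCALE_RAW

__all__ = ["ProbeAnnotation", "collapse_probes", "trimmed_mean", "normalize_and_log"]

logger = logging.getLogger(__name__)


class ProbeAnnotation:
    """Mapping probe id -> gene symbol; empty/missing symbol = unannotated."""

    def __init__(self, mapping: Mapping[str, str] | Sequence[tuple[str, str]]):
        items = mapping.items() if hasattr(mapping, "items") else mapping
        self._mapping: dict[str, str] = {}
        for probe, symbol in items:
            probe = str(probe).strip()
            if probe in self._mapping:
                raise ValueError(f"duplicate probe id in annotation: {probe!r}")
            symbol = "" if symbol is None else str(symbol).strip()
            self._mapping[probe] = symbol

    def symbol_for(self, probe: str) -> str | None:
        """Gene symbol for a probe, or None if unannotated/unknown."""
        symbol = self._mapping.get(probe, "")
        return symbol or None

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()


def collapse_probes(matrix: ExpressionMatrix, annotation: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse a probe-level raw matrix to gene level.

    Unannotated probes are dropped; when several probes map to one gene
    symbol, the per-sample value is the arithmetic mean of their raw
    intensities.
    """
    symbols = [annotation.symbol_for(p) for p in matrix.genes]
    keep = [s is not None for s in symbols]
    n_dropped = len(keep) - sum(keep)
    if n_dropped:
        logger.warning("DROPPED_PROBES\tcount=%d", n_dropped)
    kept = matrix.data.loc[keep]
    kept_symbols = [s for s in symbols if s is not None]
    if kept.empty:
        raise ValueError("empty result: no probe maps to any gene symbol")
    collapsed = kept.groupby(pd.Index(kept_symbols, name="gene"), sort=True).mean()
    return ExpressionMatrix(collapsed, scale=matrix.scale)


def trimmed_mean(values: Sequence[float] | np.ndarray, fraction: float = 0.02) -> float:
    """Mean after discarding the lowest and highest ``fraction`` of values.

    Exactly ``k = floor(fraction * m)`` values are removed from each end of
    the sorted list (ties broken by sorted position); ``fraction = 0``
    leaves the plain mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("trimmed_mean of an empty list")
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must satisfy 0 <= fraction < 0.5")
    k = math.floor(fraction * arr.size)
    if k == 0:
        return float(arr.mean())
    ordered = np.sort(arr)
    return float(ordered[k:-k].mean())


def normalize_and_log(matrix: ExpressionMatrix, fraction: float = 0.02) -> ExpressionMatrix:
    """Divide each sample by its trimmed mean, then log2-transform.

    After normalization the trimmed mean of every sample equals 1, so its
    log2 is 0; the whole chain is invariant to per-sample rescaling.
    """
    if matrix.scale != SCALE_RAW:
        raise ValueError(f"expected a raw-intensity matrix, got scale={matrix.scale!r}")
    values = matrix.data.to_numpy(dtype=float)
    if (values <= 0).any():
        rows, cols = np.nonzero(values <= 0)
        raise ValueError(
            f"nonpositive value at gene={matrix.genes[rows[0]]!r} "
            f"sample={matrix.samples[cols[0]]!r}"
        )
    divisors = np.array([trimmed_mean(values[:, j], fraction) for j in range(values.shape[1])])
    logged = np.log2(values / divisors)
    return ExpressionMatrix(
        pd.DataFrame(logged, index=matrix.genes, columns=matrix.samples),
        scale=SCALE_LOG2,
    )
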