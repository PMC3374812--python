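"""Robust per-batch scaling and quantile outlier calling (COPA-style).

Each gene is median-centred and divided by its raw median absolute deviation
(no 1.4826 consistency factor) separately within every batch, so batches with
different locations and scales contribute comparably. Outliers are samples
whose scaled value falls strictly beyond per-gene quantile cutoffs
(defaults 10%/90%, linear-interpolation quantile estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass(frozen=True)
class OutlierConfig:
    """Quantile cutoffs and the informativeness filter.

    q_low/q_high: per-gene quantile cutoffs; values strictly below/above are
    low/high outliers. min_outliers: genes with fewer total outliers in a
    matrix are discarded as uninformative. quantile_scope: whether cutoffs are
    computed within each batch ("per_batch", matching the per-batch scaling)
    or on the concatenated cohort ("pooled").
    """

    q_low: float = 0.10
    q_high: float = 0.90
    min_outliers: int = 10
    quantile_scope: Literal["per_batch", "pooled"] = "per_batch"
    mad_consistency: bool = False  # True applies the 1.4826 normal-consistency factor

    def __post_init__(self) -> None:
        if not (0.0 < self.q_low < 0.5):
            raise ValueError("q_low must be in (0, 0.5)")
        if not (0.5 < self.q_high < 1.0):
            raise ValueError("q_high must be in (0.5, 1)")
        if self.q_low >= self.q_high:
            raise ValueError("q_low must be < q_high")
        if self.min_outliers < 0:
            raise ValueError("min_outliers must be >= 0")


@dataclass
class NormalizationParams:
    """Per (gene, batch) robust location/scale used by :func:`robust_scale`.

    ``median`` and ``mad`` are gene-by-batch DataFrames; ``degenerate`` marks
    (gene, batch) cells whose MAD was zero — those cells are excluded from
    outlier calling (scaled values set to NaN).
    """

    median: pd.DataFrame
    mad: pd.DataFrame
    degenerate: pd.DataFrame


@dataclass
class OutlierMatrixPair:
    """Binary high/low outlier matrices (genes x samples) with provenance."""

    b_high: pd.DataFrame
    b_low: pd.DataFrame
    config: OutlierConfig
    removed_high: list = field(default_factory=list)
    removed_low: list = field(default_factory=list)

    def __post_init__(self) -> None:
        common = self.b_high.index.intersection(self.b_low.index)
        overlap = (self.b_high.loc[common] & self.b_low.loc[common])
        if overlap.to_numpy().any():
            raise ValueError("a value cannot be both a high and a low outlier")


def robust_scale(matrix: ExpressionMatrix, consistency: bool = False) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Median-centre and MAD-scale every gene independently within each batch.

    Missing values are ignored in the median/MAD and stay missing. A (gene,
    batch) with MAD 0 is flagged degenerate and its scaled values are set to
    NaN so it produces no outlier calls in that batch.
    """
    factor = 1.4826 if consistency else 1.0
    batches = matrix.batch_names
    med = pd.DataFrame(index=matrix.values.index, columns=batches, dtype=float)
    mad = pd.DataFrame(index=matrix.values.index, columns=batches, dtype=float)
    scaled = matrix.values.copy()
    for batch in batches:
        cols = matrix.batch_columns(batch)
        block = matrix.values[cols]
        n_ok = block.notna().sum(axis=1)
        if (n_ok < 3).any():
            bad = block.index[n_ok < 3].tolist()
            raise ValueError(f"genes with <3 non-missing values in batch {batch!r}: {bad[:10]}")
        m = block.median(axis=1, skipna=True)
        s = (block.sub(m, axis=0)).abs().median(axis=1, skipna=True) * factor
        med[batch] = m
        mad[batch] = s
        with np.errstate(divide="ignore", invalid="ignore"):
            z = block.sub(m, axis=0).div(s, axis=0)
        z[s == 0] = np.nan
        scaled[cols] = z
    degenerate = mad == 0
    params = NormalizationParams(median=med, mad=mad, degenerate=degenerate)
    return ExpressionMatrix(values=scaled, batches=matrix.batches.copy()), params


def _flag_block(block: pd.DataFrame, q_low: float, q_high: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    lo = block.quantile(q_low, axis=1, interpolation="linear")
    hi = block.quantile(q_high, axis=1, interpolation="linear")
    high = block.gt(hi, axis=0).astype(np.int8)
    low = block.lt(lo, axis=0).astype(np.int8)
    return high, low


def call_outliers(scaled: ExpressionMatrix, config: OutlierConfig | None = None) -> OutlierMatrixPair:
    """Call per-gene quantile outliers on a robust-scaled matrix.

    Cutoffs use the linear-interpolation quantile estimator; a sample is an
    outlier only if strictly beyond the cutoff, so constant genes produce no
    calls. Missing (incl. degenerate-MAD) cells are never outliers.
    """
    config = config or OutlierConfig()
    if config.quantile_scope == "pooled":
        high, low = _flag_block(scaled.values, config.q_low, config.q_high)
    else:
        highs, lows = [], []
        for batch in scaled.batch_names:
            cols = scaled.batch_columns(batch)
            h, l = _flag_block(scaled.values[cols], config.q_low, config.q_high)
            highs.append(h)
            lows.append(l)
        high = pd.concat(highs, axis=1)[scaled.sample_ids]
        low = pd.concat(lows, axis=1)[scaled.sample_ids]
    return OutlierMatrixPair(b_high=high, b_low=low, config=config)


def write_outlier_pair(pair: OutlierMatrixPair, high_path, low_path) -> None:
    """Serialize both binary matrices as dense TSV with a one-line JSON
    provenance header (the OutlierConfig used) prefixed as a ``#`` comment."""
    import json
    from dataclasses import asdict

    header = "# " + json.dumps(asdict(pair.config)) + "\n"
    for mat, path in ((pair.b_high, high_path), (pair.b_low, low_path)):
        with open(path, "w") as fh:
            fh.write(header)
            mat.to_csv(fh, sep="\t", index_label="gene_id")


def read_outlier_pair(high_path, low_path) -> OutlierMatrixPair:
    import json

    def _read(path):
        with open(path) as fh:
            header = fh.readline()
            cfg = OutlierConfig(**json.loads(header.lstrip("# ")))
            mat = pd.read_csv(fh, sep="\t", index_col=0).astype(np.int8)
        return mat, cfg

    b_high, cfg = _read(high_path)
    b_low, _ = _read(low_path)
    return OutlierMatrixPair(b_high=b_high, b_low=b_low, config=cfg)


def filter_informative(pair: OutlierMatrixPair, min_outliers: int | None = None) -> OutlierMatrixPair:
    """Drop genes with fewer than ``min_outliers`` outliers, independently in
    the high and low matrices; removed gene lists are kept for reporting."""
    if min_outliers is None:
        min_outliers = pair.config.min_outliers
    keep_h = pair.b_high.sum(axis=1) >= min_outliers
    keep_l = pair.b_low.sum(axis=1) >= min_outliers
    return OutlierMatrixPair(
        b_high=pair.b_high.loc[keep_h].copy(),
        b_low=pair.b_low.loc[keep_l].copy(),
        config=pair.config,
        removed_high=pair.b_high.index[~keep_h].tolist(),
        removed_low=pair.b_low.index[~keep_l].tolist(),
    )
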