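"""Relative recurrence score and FISH spot-count classification.

The relative recurrence score is an array-based analog of the 21-gene
RT-PCR recurrence score: genes are z-normalised per batch, averaged within
their published groups (HER2, hormonal, proliferation, invasion) and combined
with the published group/gene weights into a single prognostic score with
mean roughly zero per batch — higher is worse.

FISH amplification is scored as the mean probe-spot count over 20 tumour
nuclei: tri-class (>4 amplified, 2-4 borderline, <2 not amplified) or
presence mode against per-region cutoffs (defaults 3.5 for 8p11.2, 4.0 for
the 17q probe, 2.8 for 8q24.3; obtainable by in-sample survival
optimisation, see :func:`optimize_fish_thresholds`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix
from .survival import log_rank_test

logger = logging.getLogger(__name__)

NO_SIGNAL = "no signal"

TRICLASS_AMPLIFIED = 4.0  # strictly above -> amplified
TRICLASS_NOT = 2.0  # strictly below -> not amplified; [2, 4] inclusive -> borderline


@dataclass
class OdxWeightTable:
    """Gene groups with group weights plus individually weighted genes."""

    groups: dict[str, tuple[list[str], float]]
    genes: dict[str, float]

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for members, _ in self.groups.values():
            out.extend(members)
        out.extend(self.genes)
        dup = pd.Index(out)
        if dup.has_duplicates:
            raise ValueError(f"genes in more than one group: {dup[dup.duplicated()].tolist()}")
        return out


def load_odx_weights(path) -> OdxWeightTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = {name: (list(spec["genes"]), float(spec["weight"]))
              for name, spec in raw.get("groups", {}).items()}
    genes = {g: float(w) for g, w in raw.get("genes", {}).items()}
    table = OdxWeightTable(groups=groups, genes=genes)
    table.all_genes()  # validates disjointness
    return table


def load_default_odx_weights() -> OdxWeightTable:
    """The packaged reference-derived 21-gene-style weight table."""
    ref = resources.files("amplimark.data").joinpath("odx_weights.yaml")
    with resources.as_file(ref) as path:
        return load_odx_weights(path)


def load_fish_example() -> pd.DataFrame:
    """A 14-sample example FISH classification table (three probes plus the
    associated recurrence score) used in the worked examples and tests."""
    ref = resources.files("amplimark.data").joinpath("fish_example.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def relative_odx_score(matrix: ExpressionMatrix, weights: OdxWeightTable | None = None) -> pd.Series:
    """Per-sample relative recurrence score.

    Every weight-table gene is z-normalised across samples within each batch
    (sample mean 0, sd 1); a group's score is the mean of its member genes and
    the final score is the weighted sum of group scores plus individually
    weighted genes. Missing genes raise (listing them); a zero-variance gene
    in a batch is excluded from its group there with a warning.
    """
    weights = weights or load_default_odx_weights()
    needed = weights.all_genes()
    missing = [g for g in needed if g not in matrix.values.index]
    if missing:
        raise ValueError(f"weight-table genes absent from expression matrix: {missing}")
    z = pd.DataFrame(index=needed, columns=matrix.sample_ids, dtype=float)
    for batch in matrix.batch_names:
        cols = matrix.batch_columns(batch)
        block = matrix.values.loc[needed, cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            logger.warning("zero-variance score genes in batch %s: %s",
                           batch, block.index[flat].tolist())
        zb = block.sub(mu, axis=0).div(sd.where(~flat), axis=0)
        z[cols] = zb
    score = pd.Series(0.0, index=matrix.sample_ids)
    for members, w in weights.groups.values():
        score += w * z.loc[members].mean(axis=0, skipna=True).fillna(0.0)
    for gene, w in weights.genes.items():
        score += w * z.loc[gene].fillna(0.0)
    return score


def dichotomize_score(scores: pd.Series, cutoff: float = 0.0) -> pd.Series:
    """Label samples 'high' when score > cutoff (strict), else 'low'."""
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return pd.Series(np.where(s > cutoff, "high", "low"), index=s.index)


@dataclass(frozen=True)
class FishThresholds:
    """Per-region presence cutoffs in mean spots/cell."""

    cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {"8p11.2": 3.5, "17q22": 4.0, "8q24.3": 2.8}
    )

    def __post_init__(self) -> None:
        for region, c in self.cutoffs.items():
            if c <= 0:
                raise ValueError(f"non-positive cutoff for {region}")


def classify_fish(counts: Mapping[str, float | str | None],
                  thresholds: FishThresholds | None = None,
                  mode: str = "triclass") -> dict:
    """Classify one sample's per-region mean spot counts.

    triclass mode: count > 4 -> 'amplified', 2 <= count <= 4 -> 'borderline',
    count < 2 -> 'not amplified'. presence mode: region positive iff count >=
    its cutoff; 'no signal' (or None/NaN) regions stay unscored and are
    excluded from the any-amplicon OR unless another region is positive.
    """
    thresholds = thresholds or FishThresholds()
    scored = {}
    for region, value in counts.items():
        if value is None or (isinstance(value, str) and value.strip().lower() == NO_SIGNAL):
            scored[region] = None
            continue
        c = float(value)
        if np.isnan(c):
            scored[region] = None
            continue
        if c < 0:
            raise ValueError(f"negative spot count for {region}: {c}")
        scored[region] = c
    if all(v is None for v in scored.values()):
        raise ValueError("no scored region in sample")
    if mode == "triclass":
        labels = {}
        for region, c in scored.items():
            if c is None:
                labels[region] = NO_SIGNAL
            elif c > TRICLASS_AMPLIFIED:
                labels[region] = "amplified"
            elif c < TRICLASS_NOT:
                labels[region] = "not amplified"
            else:
                labels[region] = "borderline"
        return labels
    if mode == "presence":
        flags = {}
        for region, c in scored.items():
            if c is None:
                flags[region] = None
            else:
                cut = thresholds.cutoffs.get(region)
                if cut is None:
                    raise ValueError(f"no presence cutoff configured for region {region!r}")
                flags[region] = int(c >= cut)
        present = [v for v in flags.values() if v is not None]
        flags["any_amplicon"] = int(any(v == 1 for v in present))
        return flags
    raise ValueError(f"unknown mode {mode!r}")


def classify_fish_table(table: pd.DataFrame, regions: Sequence[str],
                        thresholds: FishThresholds | None = None,
                        mode: str = "presence") -> pd.DataFrame:
    """Vector form of :func:`classify_fish` over a sample x region count table."""
    rows = {}
    for sid, row in table.set_index("sample_id")[list(regions)].iterrows():
        rows[sid] = classify_fish(row.to_dict(), thresholds, mode=mode)
    return pd.DataFrame.from_dict(rows, orient="index")


def optimize_fish_thresholds(
    fish: pd.DataFrame,
    clinical: pd.DataFrame,
    grids: Mapping[str, Sequence[float]],
) -> tuple[FishThresholds, pd.DataFrame]:
    """Exhaustive grid search for the per-region cutoffs maximising the
    log-rank statistic of any-amplicon vs no-amplicon survival.

    This is in-sample optimisation (the trace is returned so the flatness of
    the objective can be inspected); ties in the statistic break toward
    larger cutoffs. ``fish`` needs sample_id plus one count column per region.
    Raises when no grid point produces two non-empty arms.
    """
    regions = list(grids)
    counts = fish.set_index("sample_id")[regions]
    clin = clinical.loc[[s for s in counts.index if s in clinical.index]]
    counts = counts.loc[clin.index]
    if counts.shape[0] < 2:
        raise ValueError("need at least two FISH-scored samples with outcomes")
    t = clin["time"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    best = None
    trace = []
    for combo in itertools.product(*(sorted(grids[r]) for r in regions)):
        pos = pd.DataFrame(
            {r: numeric[r] >= c for r, c in zip(regions, combo)}, index=numeric.index
        )
        scored = numeric.notna()
        any_amp = (pos & scored).any(axis=1).to_numpy()
        callable_mask = scored.any(axis=1).to_numpy()
        a = any_amp & callable_mask
        b = ~any_amp & callable_mask
        if a.sum() == 0 or b.sum() == 0:
            trace.append((*combo, np.nan))
            continue
        stat, _ = log_rank_test(t[a], e[a], t[b], e[b])
        trace.append((*combo, stat))
        if best is None or stat >= best[0]:
            best = (stat, combo)
    trace_df = pd.DataFrame(trace, columns=[*regions, "logrank_stat"])
    if best is None:
        raise ValueError("no grid point yields two non-empty arms")
    chosen = FishThresholds(cutoffs=dict(zip(regions, best[1])))
    return chosen, trace_df
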