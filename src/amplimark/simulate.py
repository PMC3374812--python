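"""Synthetic multi-batch tumour cohorts with planted amplicons and ground truth.

The generator emulates the data structure the pipeline is designed for:
heavy-tailed (Student-t) log2 expression with batch-specific location/scale,
contiguous blocks of chromosome-adjacent genes over-expressed in a carrier
subset of samples (the planted amplicons), a diffuse "cell-cycle" gene set
co-elevated in carrier samples, and exponential survival whose hazard is
multiplied by each carried amplicon's hazard ratio, with independent uniform
censoring. Every random draw flows from one seed, so identical configurations
reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, validate_annotation, validate_clinical


@dataclass(frozen=True)
class AmpliconSpec:
    """A planted amplicon: a contiguous run of genes on one chromosome.

    start/length index into the chromosome's position-sorted genes; carriers
    (a Bernoulli(prevalence) subset of samples) get +shift_mad x per-gene MAD
    added to every span gene, and their event hazard is multiplied by
    hazard_ratio.
    """

    name: str
    chrom: str
    start: int
    length: int
    prevalence: float
    shift_mad: float = 4.0
    hazard_ratio: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.shift_mad <= 0 or self.hazard_ratio <= 0:
            raise ValueError("shift_mad and hazard_ratio must be positive")
        if self.length < 1 or self.start < 0:
            raise ValueError("invalid span")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_chromosomes: int = 4
    batches: Mapping[str, int] = field(default_factory=lambda: {"A": 100, "B": 100, "C": 100})
    amplicons: tuple[AmpliconSpec, ...] = ()
    cellcycle_size: int = 40
    cellcycle_prob: float = 0.7  # per carrier sample, probability of co-elevation
    cellcycle_shift: float = 3.0  # in per-gene MAD units
    baseline_hazard: float = 0.04  # events per year for amplicon-free samples
    censoring_rate: float = 0.30  # target fraction censored (independent uniform censoring)
    t_df: float = 5.0  # Student-t degrees of freedom of the background noise
    seed: int = 0

    def __post_init__(self) -> None:
        spans: dict[str, list[tuple[int, int]]] = {}
        for amp in self.amplicons:
            spans.setdefault(amp.chrom, []).append((amp.start, amp.start + amp.length))
        for chrom, ivals in spans.items():
            ivals.sort()
            for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
                if a2 < b1:
                    raise ValueError(f"overlapping amplicon spans on {chrom}")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth for recovery testing."""

    carriers: pd.DataFrame  # samples x amplicon names, 0/1
    region_genes: dict[str, list[str]]  # amplicon name -> span gene ids
    hazard_ratios: dict[str, float]
    cellcycle_genes: list[str]
    cellcycle_active: pd.Series  # samples, 0/1
    config: SimulationConfig


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard test fixture: 2000 genes on 4 chromosomes, 3 batches of
    100 samples, two planted 25-gene amplicons (prevalence 0.25, shift 4 MAD,
    hazard ratio 4)."""
    amps = (
        AmpliconSpec("ampA", "chr1", 120, 25, prevalence=0.25, shift_mad=4.0, hazard_ratio=4.0),
        AmpliconSpec("ampB", "chr2", 300, 25, prevalence=0.25, shift_mad=4.0, hazard_ratio=4.0),
    )
    return SimulationConfig(amplicons=amps, seed=seed, **overrides)


def _solve_censor_horizon(hazards: np.ndarray, rate: float) -> float:
    """Horizon tau of U(0, tau) censoring giving the target mean censoring
    fraction for exponential event times with the given per-sample hazards."""

    def mean_censored(tau: float) -> float:
        lt = hazards * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    return brentq(lambda tau: mean_censored(tau) - rate, 1e-9, 1e9, xtol=1e-10)


def simulate_cohort(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (expression, annotation, clinical, truth) for one cohort."""
    rng = np.random.default_rng(config.seed)
    # --- gene map: evenly split genes over chromosomes, fixed spacing ---
    per_chrom = config.n_genes // config.n_chromosomes
    chroms, gene_ids, starts, ends, bands = [], [], [], [], []
    gi = 0
    for c in range(config.n_chromosomes):
        n_c = per_chrom if c < config.n_chromosomes - 1 else config.n_genes - per_chrom * (config.n_chromosomes - 1)
        chrom = f"chr{c + 1}"
        for j in range(n_c):
            gene_ids.append(f"G{gi:05d}")
            chroms.append(chrom)
            starts.append(100_000 + 50_000 * j)
            ends.append(100_000 + 50_000 * j + 20_000)
            bands.append(f"{c + 1}q{j // 25 + 1}")
            gi += 1
    annotation = validate_annotation(pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chroms, "start": starts, "end": ends, "cytoband": bands}
    ))
    by_chrom = {c: g.sort_values("start")["gene_id"].tolist() for c, g in annotation.groupby("chrom")}

    sample_ids, batch_labels = [], []
    for bname, size in config.batches.items():
        for k in range(size):
            sample_ids.append(f"{bname}{k:03d}")
            batch_labels.append(bname)
    n_samples = len(sample_ids)
    batches = pd.Series(batch_labels, index=sample_ids)

    # --- background: per-batch location/scale around heavy-tailed noise ---
    values = np.empty((config.n_genes, n_samples))
    col = 0
    for bi, (bname, size) in enumerate(config.batches.items()):
        loc = 8.0 + 0.3 * bi
        scale = 1.0 + 0.15 * bi
        values[:, col : col + size] = loc + scale * rng.standard_t(config.t_df, size=(config.n_genes, size))
        col += size
    values_df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    # per (gene, batch) MAD of the background, the unit of the planted shifts
    batch_cols = {}
    c0 = 0
    for bname, size in config.batches.items():
        batch_cols[bname] = np.arange(c0, c0 + size)
        c0 += size
    mad = {}
    for bname, idx in batch_cols.items():
        block = values[:, idx]
        med = np.median(block, axis=1, keepdims=True)
        mad[bname] = np.median(np.abs(block - med), axis=1)

    # --- plant amplicons ---
    carriers = pd.DataFrame(0, index=sample_ids, columns=[a.name for a in config.amplicons], dtype=int)
    region_genes: dict[str, list[str]] = {}
    for amp in config.amplicons:
        genes_c = by_chrom[amp.chrom]
        if amp.start + amp.length > len(genes_c):
            raise ValueError(f"amplicon {amp.name} span exceeds chromosome {amp.chrom}")
        span = genes_c[amp.start : amp.start + amp.length]
        region_genes[amp.name] = span
        carry = rng.random(n_samples) < amp.prevalence
        carriers[amp.name] = carry.astype(int)
        rows = np.array([gene_pos[g] for g in span])
        for bname, idx in batch_cols.items():
            cset = idx[carry[idx]]
            if cset.size:
                values[np.ix_(rows, cset)] += amp.shift_mad * mad[bname][rows][:, None]

    # --- diffuse cell-cycle set co-elevated in carriers ---
    in_amplicon = {g for span in region_genes.values() for g in span}
    free = [g for g in gene_ids if g not in in_amplicon]
    cc_genes = sorted(rng.choice(free, size=min(config.cellcycle_size, len(free)), replace=False))
    any_carrier = carriers.sum(axis=1).to_numpy() > 0
    cc_active = any_carrier & (rng.random(n_samples) < config.cellcycle_prob)
    if cc_genes and cc_active.any():
        rows = np.array([gene_pos[g] for g in cc_genes])
        for bname, idx in batch_cols.items():
            aset = idx[cc_active[idx]]
            if aset.size:
                values[np.ix_(rows, aset)] += config.cellcycle_shift * mad[bname][rows][:, None]

    expression = ExpressionMatrix(values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
                                  batches=batches)

    # --- survival: exponential with multiplicative amplicon hazards ---
    log_hr = np.zeros(n_samples)
    for amp in config.amplicons:
        log_hr += np.log(amp.hazard_ratio) * carriers[amp.name].to_numpy()
    hazards = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        tau = _solve_censor_horizon(hazards, config.censoring_rate)
        t_cens = rng.uniform(0.0, tau, size=n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_samples, dtype=int)

    n_amp = carriers.sum(axis=1).to_numpy()
    grade_probs = np.where(n_amp[:, None] > 0, [[0.15, 0.45, 0.40]], [[0.40, 0.45, 0.15]])
    grade_idx = (rng.random(n_samples)[:, None] > np.cumsum(grade_probs, axis=1)).sum(axis=1)
    grades = np.array(["low", "intermediate", "high"])[grade_idx]
    clinical = validate_clinical(pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "age": np.round(rng.normal(61.0, 9.0, n_samples), 1),
            "tumor_size": rng.integers(1, 5, n_samples),
            "grade": grades,
            "node_negative": rng.integers(0, 2, n_samples),
            "her2": rng.binomial(1, 0.15, n_samples),
            "er": np.ones(n_samples, dtype=int),
        }
    ))
    truth = SimulationTruth(
        carriers=carriers,
        region_genes=region_genes,
        hazard_ratios={a.name: a.hazard_ratio for a in config.amplicons},
        cellcycle_genes=list(cc_genes),
        cellcycle_active=pd.Series(cc_active.astype(int), index=sample_ids),
        config=config,
    )
    return expression, annotation, clinical, truth


def simulate_fish_counts(
    truth: SimulationTruth,
    cutoffs: Mapping[str, float] | None = None,
    noise_sd: float = 0.3,
    dropout_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean spot counts per sample per planted region, as a FISH assay would
    report them: carriers one half-spot above the presence cutoff plus noise,
    non-carriers around the diploid two spots/cell, with 'no signal' dropouts
    at the stated rate. With noise_sd 0 the presence classifier separates
    carriers from non-carriers perfectly.
    """
    rng = np.random.default_rng(seed)
    regions = list(truth.carriers.columns)
    cutoffs = dict(cutoffs or {r: 3.5 for r in regions})
    out = pd.DataFrame(index=truth.carriers.index, columns=regions, dtype=object)
    for r in regions:
        carry = truth.carriers[r].to_numpy().astype(bool)
        counts = np.where(
            carry,
            cutoffs[r] + 0.5 + rng.normal(0.0, noise_sd, carry.size),
            2.0 + rng.normal(0.0, noise_sd / 2 if noise_sd else 0.0, carry.size),
        )
        counts = np.clip(counts, 0.0, None)
        drop = rng.random(carry.size) < dropout_rate
        vals: list[object] = [float(c) for c in counts]
        for i in np.flatnonzero(drop):
            vals[i] = "no signal"
        out[r] = vals
    out.insert(0, "sample_id", out.index)
    return out.reset_index(drop=True)
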