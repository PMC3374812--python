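"""Model/Results surface and end-to-end pipeline orchestration.

:class:`AmpliconRelapseModel` bundles a cohort (expression, gene annotation,
clinical follow-up) with the analysis configuration; ``fit()`` executes the
whole chain — per-batch robust scaling, quantile outlier calling, the
per-gene survival screen, phi-graph clustering, sliding-window amplicon
definition, per-sample amplicon calls and carrier-vs-none survival — and
returns an :class:`AmpliconRelapseResults` with estimates, uncertainties and
a ``summary()`` table. :func:`run_pipeline` is the file-based wrapper the CLI
uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .clustering import GeneClusterSet, PruneConfig, pca_clusters, phi_matrix, prune_correlation_graph
from .io import (
    ExpressionMatrix,
    merge_batches,
    read_clinical_table,
    read_expression_table,
    read_gene_annotation,
)
from .outliers import OutlierConfig, OutlierMatrixPair, call_outliers, filter_informative, robust_scale
from .regions import (
    AmpliconDefinition,
    WindowConfig,
    call_amplicons_per_sample,
    define_amplicons,
    stratified_outcome,
)
from .scores import OdxWeightTable, relative_odx_score
from .survival import outlier_survival_screen

logger = logging.getLogger(__name__)


@dataclass
class AmpliconRelapseResults:
    """Fitted pipeline outputs.

    Attributes
    ----------
    associations : per-gene survival screen hits (gene, direction, HR, CI, p).
    clusters : phi-graph cluster sets per direction ('high'/'low'), or None
        when too few genes survived.
    amplicons : merged significant regions with their marker genes.
    enrichment : the full window enrichment table (k, p, q per window).
    calls : samples x amplicons binary matrix with ``any_amplicon``.
    stratified : carrier-vs-no-amplicon hazard ratios and log-rank tests.
    curves : per-amplicon (carrier, reference) Kaplan-Meier curves.
    odx_scores : per-sample relative recurrence score, when weights were given.
    """

    model: "AmpliconRelapseModel"
    associations: pd.DataFrame
    clusters: dict[str, GeneClusterSet | None]
    poor_cluster_genes: list[str]
    amplicons: list[AmpliconDefinition]
    enrichment: pd.DataFrame
    calls: pd.DataFrame
    stratified: pd.DataFrame | None
    curves: dict
    odx_scores: pd.Series | None
    outlier_pair: OutlierMatrixPair

    @property
    def amplicon_names(self) -> list[str]:
        return [a.name for a in self.amplicons]

    def summary(self) -> str:
        m = self.model
        lines = [
            "Amplicon outlier-expression analysis",
            "=" * 48,
            f"samples: {len(m.expression.sample_ids)}   genes: {len(m.expression.gene_ids)}   "
            f"batches: {len(m.expression.batch_names)}",
            f"outlier cutoffs: q_low={m.outlier_config.q_low}, q_high={m.outlier_config.q_high}, "
            f"min_outliers={m.outlier_config.min_outliers}",
            f"screen: log-rank p < {m.alpha}; hits: "
            f"{(self.associations['direction'] == 'high').sum()} high, "
            f"{(self.associations['direction'] == 'low').sum()} low",
            f"amplicon regions (window {m.window_config.width}/pace {m.window_config.pace}, "
            f"FDR {m.window_config.fdr}): {len(self.amplicons)}",
        ]
        for a in self.amplicons:
            freq = float(self.calls[a.name].mean()) if a.name in self.calls else float("nan")
            lines.append(f"  {a.name}  ({a.chrom})  markers={len(a.marker_genes)}  "
                         f"carrier frequency={freq:.3f}")
        if self.stratified is not None and not self.stratified.empty:
            lines.append("carrier vs no-amplicon survival:")
            for _, r in self.stratified.iterrows():
                lines.append(
                    f"  {r['amplicon']:<14} HR={r['hazard_ratio']:.2f} "
                    f"(95% CI {r['hr_ci_lower']:.2f}-{r['hr_ci_upper']:.2f})  "
                    f"log-rank p={r['p_value']:.2e}  n={r['n_carrier']} vs {r['n_reference']}"
                )
        return "\n".join(lines)


@dataclass
class AmpliconRelapseModel:
    """Supervised outlier-expression model of amplicon-driven early relapse.

    Parameters mirror the analysis stages: quantile outlier calling
    (``outlier_config``), the survival screen significance level (``alpha``),
    phi-graph pruning (``prune_config``) and sliding-window region detection
    (``window_config``). ``odx_weights`` optionally enables the relative
    recurrence score stage.
    """

    expression: ExpressionMatrix
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    outlier_config: OutlierConfig = field(default_factory=OutlierConfig)
    prune_config: PruneConfig = field(default_factory=PruneConfig)
    window_config: WindowConfig = field(default_factory=WindowConfig)
    alpha: float = 0.05
    call_mode: str = "fisher"  # per-array region enrichment; "fraction" = >=50%-markers rule
    odx_weights: OdxWeightTable | None = None

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, batches: pd.Series,
                        annotation: pd.DataFrame, clinical: pd.DataFrame, **kwargs):
        return cls(ExpressionMatrix(values=expression, batches=batches),
                   annotation, clinical, **kwargs)

    def fit(self) -> AmpliconRelapseResults:
        matrix = self.expression
        samples = set(matrix.sample_ids)
        missing = samples - set(self.clinical.index)
        if missing:
            raise ValueError(f"samples without clinical records: {sorted(missing)[:10]}")

        scaled, _params = robust_scale(matrix)
        pair = call_outliers(scaled, self.outlier_config)
        filtered = filter_informative(pair)
        associations = outlier_survival_screen(filtered, self.clinical, alpha=self.alpha)

        clusters: dict[str, GeneClusterSet | None] = {"high": None, "low": None}
        poor_genes: list[str] = []
        for direction, mat in (("high", filtered.b_high), ("low", filtered.b_low)):
            hits = associations.loc[associations["direction"] == direction]
            genes = [g for g in hits["gene_id"] if g in mat.index]
            if len(genes) < 2:
                continue
            sub = mat.loc[genes]
            phi = phi_matrix(sub)
            retained = prune_correlation_graph(phi, self.prune_config)
            if len(retained) < 2:
                continue
            hr = hits.set_index("gene_id")["hazard_ratio"]
            cset = pca_clusters(sub.loc[retained], hr_direction=hr, config=self.prune_config)
            clusters[direction] = cset
            if direction == "high":
                for cid, members in cset.clusters.items():
                    if cset.prognosis[cid] == "poor":
                        poor_genes.extend(members)

        universe = matrix.gene_ids
        ann = self.annotation[self.annotation["gene_id"].isin(universe)]
        if poor_genes:
            amplicons, enrichment = define_amplicons(poor_genes, ann, universe, self.window_config)
        else:
            amplicons, enrichment = [], pd.DataFrame(
                columns=["window", "chrom", "start_index", "stop_index", "k", "set_size", "p", "q"])

        if amplicons:
            calls = call_amplicons_per_sample(pair.b_high, amplicons, mode=self.call_mode,
                                              fdr=self.window_config.fdr)
        else:
            calls = pd.DataFrame({"any_amplicon": 0}, index=matrix.sample_ids)

        stratified, curves = None, {}
        if amplicons and calls["any_amplicon"].sum() > 0 and (calls["any_amplicon"] == 0).sum() > 0:
            try:
                stratified, curves = stratified_outcome(calls, self.clinical)
            except ValueError as exc:  # e.g. a region with zero carriers
                logger.warning("stratified outcome unavailable: %s", exc)

        odx = None
        if self.odx_weights is not None:
            odx = relative_odx_score(matrix, self.odx_weights)

        return AmpliconRelapseResults(
            model=self,
            associations=associations,
            clusters=clusters,
            poor_cluster_genes=sorted(set(poor_genes)),
            amplicons=amplicons,
            enrichment=enrichment,
            calls=calls,
            stratified=stratified,
            curves=curves,
            odx_scores=odx,
            outlier_pair=filtered,
        )


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (one YAML document)."""

    expression: list[dict]  # [{path: ..., batch: ...}, ...]
    annotation: str
    clinical: str
    out_dir: str
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    alpha: float = 0.05
    call_mode: str = "fisher"
    odx_weights: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            expression=raw["expression"],
            annotation=raw["annotation"],
            clinical=raw["clinical"],
            out_dir=raw.get("out_dir", "amplimark_out"),
            outlier=OutlierConfig(**raw.get("outlier", {})),
            prune=PruneConfig(**raw.get("prune", {})),
            window=WindowConfig(**raw.get("window", {})),
            alpha=float(raw.get("alpha", 0.05)),
            call_mode=raw.get("call_mode", "fisher"),
            odx_weights=raw.get("odx_weights"),
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        paths = [e["path"] for e in self.expression] + [self.annotation, self.clinical]
        if self.odx_weights:
            paths.append(self.odx_weights)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute ingest -> outliers -> screen -> cluster -> regions -> calls ->
    stratified outcome -> scores, writing every stage table plus a JSON
    summary under ``config.out_dir``. Returns the summary dict."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrices = [read_expression_table(e["path"], e["batch"]) for e in config.expression]
    matrix = merge_batches(matrices)
    annotation = read_gene_annotation(config.annotation)
    clinical = read_clinical_table(config.clinical)

    weights = None
    if config.odx_weights:
        from .scores import load_odx_weights

        weights = load_odx_weights(config.odx_weights)

    model = AmpliconRelapseModel(
        expression=matrix,
        annotation=annotation,
        clinical=clinical,
        outlier_config=config.outlier,
        prune_config=config.prune,
        window_config=config.window,
        alpha=config.alpha,
        call_mode=config.call_mode,
        odx_weights=weights,
    )
    res = model.fit()

    res.associations.to_csv(out / "screen_associations.tsv", sep="\t", index=False)
    res.enrichment.to_csv(out / "window_enrichment.tsv", sep="\t", index=False)
    res.calls.to_csv(out / "amplicon_calls.tsv", sep="\t", index_label="sample_id")
    if res.stratified is not None:
        res.stratified.to_csv(out / "stratified_outcome.tsv", sep="\t", index=False)
    amp_rows = [
        {"name": a.name, "chrom": a.chrom, "start_bp": a.start_bp, "end_bp": a.end_bp,
         "n_markers": len(a.marker_genes), "marker_genes": ",".join(a.marker_genes)}
        for a in res.amplicons
    ]
    pd.DataFrame(amp_rows, columns=["name", "chrom", "start_bp", "end_bp", "n_markers",
                                    "marker_genes"]).to_csv(out / "amplicons.tsv", sep="\t", index=False)
    if res.odx_scores is not None:
        res.odx_scores.rename("odx_score").to_csv(out / "odx_scores.tsv", sep="\t",
                                                  index_label="sample_id")

    summary = {
        "version": _pkg_version,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_samples": len(matrix.sample_ids),
        "n_genes": len(matrix.gene_ids),
        "n_screen_hits": int(res.associations.shape[0]),
        "amplicons": [
            {"name": a.name, "chrom": a.chrom, "n_markers": len(a.marker_genes),
             "carrier_frequency": float(res.calls[a.name].mean()) if a.name in res.calls else None}
            for a in res.amplicons
        ],
        "stratified": (res.stratified.to_dict(orient="records") if res.stratified is not None else []),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    (out / "run_log.txt").write_text(
        f"amplimark {_pkg_version}\nseed {config.seed}\nconfig {_config_hash(config)}\n"
        f"summary: {res.summary()}\n"
    )
    return summary
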