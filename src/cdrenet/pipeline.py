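"""End-to-end orchestration: expression -> MI network -> metrics ->
Commodore classification -> enrichment, for two conditions, plus the
side-by-side summary report.

A single :class:`PipelineConfig` drives a run, sourcing data either from
TSV files (one miR and one gene matrix per condition) or from the synthetic
generator. Every stage parameter is echoed into a provenance record so a
bundle can be reproduced exactly from its own output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import classifier as clf
from . import enrichment as enr
from . import metrics as met
from . import mi_network as min_
from . import preprocessing as prep
from . import synthetic as syn
from .errors import ConfigurationError, DomainError

log = logging.getLogger("cdrenet")


@dataclass
class PipelineConfig:
    """Everything a full two-condition run needs; exactly one data source."""

    # data source: either a synthetic spec ...
    synthetic: syn.SyntheticConfig | None = None
    # ... or four expression tables
    mir_a_path: str | None = None
    gene_a_path: str | None = None
    mir_b_path: str | None = None
    gene_b_path: str | None = None
    annotation_path: str | None = None

    condition_a: str = "A"
    condition_b: str = "B"

    quantile: float = min_.DEFAULT_QUANTILE
    n_bins: int | None = None  # None = ceil(sqrt(n_samples)) capped at 20
    pseudocount: float = 1.0
    min_shared_samples: int = 10
    degree_min: int = 100
    redundancy_max: float = 0.5
    strict_thresholds: bool = True
    ora_min_size: int = 5
    ora_max_size: int = 2000
    ora_top: int = 10

    # synthetic-annotation knobs (used only with a synthetic source)
    n_categories: int = 150
    category_size_range: tuple[int, int] = (10, 100)

    out_dir: str | None = None

    def __post_init__(self) -> None:
        paths = [self.mir_a_path, self.gene_a_path, self.mir_b_path, self.gene_b_path]
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.synthetic is not None and some_paths:
            raise ConfigurationError(
                "provide either a synthetic spec or input paths, not both"
            )
        if self.synthetic is None and not has_paths:
            raise ConfigurationError(
                "provide a synthetic spec or all four expression table paths"
            )
        if not (0.0 < self.quantile < 1.0):
            raise ConfigurationError("quantile must lie in (0, 1)")
        if self.degree_min < 0 or not (0.0 <= self.redundancy_max <= 1.0):
            raise ConfigurationError("classification thresholds out of domain")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_size_range"] = list(self.category_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = syn.SyntheticConfig(**d["synthetic"])
        if d.get("category_size_range") is not None:
            d["category_size_range"] = tuple(d["category_size_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ConditionResult:
    """Artifacts of one condition's analysis."""

    label: str
    network: nx.Graph
    metrics: pd.DataFrame
    summary: met.NetworkSummary
    cdre: clf.CdreReport
    neighborhoods: dict[str, set[str]]
    intersections: pd.DataFrame
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    intersection_enrichment: dict[tuple[str, str], pd.DataFrame] = field(
        default_factory=dict
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    condition_a: ConditionResult
    condition_b: ConditionResult
    lfc: pd.Series
    comparison: pd.DataFrame
    truth: syn.GroundTruth | None = None


def _analyze_condition(
    label: str,
    mir: prep.ExpressionMatrix,
    gene: prep.ExpressionMatrix,
    lfc: pd.Series,
    catalog: enr.AnnotationCatalog | None,
    config: PipelineConfig,
) -> ConditionResult:
    log.info("=== condition %s ===", label)
    mir, gene = prep.align_samples(mir, gene, config.min_shared_samples)
    mir_log = prep.log_transform(mir, config.pseudocount)
    gene_log = prep.log_transform(gene, config.pseudocount)
    result = min_.all_pairs_mi(mir_log, gene_log, config.n_bins)
    edges = min_.percentile_filter(result, config.quantile)
    G = min_.build_bipartite_network(edges, lfc)
    metrics = met.node_metrics(G)
    summary = met.summarize(G, metrics)
    cdre = clf.classify_mirs(
        metrics, config.degree_min, config.redundancy_max, config.strict_thresholds
    )
    neighborhoods = clf.extract_neighborhoods(G, cdre.commodores)
    intersections = clf.neighborhood_intersections(neighborhoods)

    enrichment: dict[str, pd.DataFrame] = {}
    pair_enrichment: dict[tuple[str, str], pd.DataFrame] = {}
    if catalog is not None and len(catalog):
        cat = catalog.restrict_universe(gene.feature_ids)
        for m, genes_ in sorted(neighborhoods.items()):
            try:
                enrichment[m] = enr.ora(
                    genes_, cat, config.ora_min_size, config.ora_max_size,
                    top=None,
                )
            except DomainError as exc:
                log.warning("ORA skipped for %s: %s", m, exc)
        for _, row in intersections.iterrows():
            shared = set(row["shared_genes"].split(";")) if row["n_shared"] else set()
            if not shared:
                continue
            try:
                pair_enrichment[(row["mir_a"], row["mir_b"])] = enr.ora(
                    shared, cat, config.ora_min_size, config.ora_max_size, top=None,
                )
            except DomainError as exc:
                log.warning(
                    "ORA skipped for intersection %s/%s: %s",
                    row["mir_a"], row["mir_b"], exc,
                )
    return ConditionResult(
        label=label,
        network=G,
        metrics=metrics,
        summary=summary,
        cdre=cdre,
        neighborhoods=neighborhoods,
        intersections=intersections,
        enrichment=enrichment,
        intersection_enrichment=pair_enrichment,
    )


def compare_summaries(
    summary_a: met.NetworkSummary,
    summary_b: met.NetworkSummary,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Side-by-side two-condition table of the standard network parameters.

    Counts are integers; means are reported rounded to 2 decimals.
    """
    rows = [
        ("Nodes, miR", "n_mir_nodes", 0),
        ("Nodes, gene", "n_gene_nodes", 0),
        ("Edges", "n_edges", 0),
        ("Average degree, miR", "mean_degree_mir", 2),
        ("Average degree, gene", "mean_degree_gene", 2),
        ("Average clustering coefficient, miR", "mean_clustering_mir", 2),
        ("Average clustering coefficient, gene", "mean_clustering_gene", 2),
        ("Average redundancy coefficient, miR", "mean_redundancy_mir", 2),
        ("Average redundancy coefficient, gene", "mean_redundancy_gene", 2),
        ("Connected components", "n_components", 0),
    ]
    data = {}
    for label, s in ((label_a, summary_a), (label_b, summary_b)):
        col = []
        for _, attr, ndigits in rows:
            v = getattr(s, attr)
            col.append(round(v, ndigits) if ndigits else v)
        data[label] = col
    out = pd.DataFrame(data, index=[name for name, _, _ in rows])
    out.index.name = "Parameter"
    return out


def _write_condition(res: ConditionResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    min_.write_gml(res.network, out / "network.gml")
    res.metrics.to_csv(out / "node_metrics.tsv", sep="\t", index=False,
                       float_format="%.6f")
    with open(out / "summary.json", "w") as fh:
        json.dump(res.summary.to_dict(), fh, indent=2, sort_keys=True,
                  default=float)
        fh.write("\n")
    res.cdre.write_tsv(out / "cdre_report.tsv")
    with open(out / "neighborhoods.json", "w") as fh:
        json.dump({m: sorted(g) for m, g in sorted(res.neighborhoods.items())},
                  fh, indent=2)
        fh.write("\n")
    res.intersections.to_csv(out / "intersections.tsv", sep="\t", index=False,
                             float_format="%.4f")
    if res.enrichment or res.intersection_enrichment:
        edir = out / "enrichment"
        edir.mkdir(exist_ok=True)
        for m, df in sorted(res.enrichment.items()):
            df.to_csv(edir / f"{m}.tsv", sep="\t", index=False, float_format="%.6g")
        for (a, b), df in sorted(res.intersection_enrichment.items()):
            df.to_csv(edir / f"{a}__{b}.tsv", sep="\t", index=False,
                      float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full two-condition analysis; write the bundle if out_dir set.

    Deterministic given the config (including the synthetic seed): rerunning
    with an identical config reproduces every output file byte for byte.
    """
    truth = None
    catalog = None
    if config.synthetic is not None:
        cond_a, cond_b, truth = syn.generate_expression_pair(config.synthetic)
        mir_a, gene_a = cond_a.mir, cond_a.gene
        mir_b, gene_b = cond_b.mir, cond_b.gene
        if config.n_categories > 0:
            planted = None
            if truth.commodore_ids:
                first = sorted(truth.commodore_ids)[0]
                targets = frozenset(truth.regulon_map[first])
                size = max(
                    config.category_size_range[0],
                    min(config.category_size_range[1], len(targets)),
                )
                overlap = min(len(targets), int(0.8 * size) or 1)
                planted = syn.PlantedEnrichment(
                    target_genes=targets, overlap=overlap, size=size,
                    category_id="planted-commodore-1",
                    description=f"planted: targets of {first}",
                )
            catalog = syn.generate_annotation(
                gene_a.feature_ids,
                n_categories=config.n_categories,
                size_range=config.category_size_range,
                planted=planted,
                rng_seed=config.synthetic.rng_seed + 10_000,
            )
    else:
        mir_a = prep.read_expression_table(config.mir_a_path, "mir", config.condition_a)
        gene_a = prep.read_expression_table(config.gene_a_path, "gene",
                                            config.condition_a)
        mir_b = prep.read_expression_table(config.mir_b_path, "mir", config.condition_b)
        gene_b = prep.read_expression_table(config.gene_b_path, "gene",
                                            config.condition_b)
        if config.annotation_path:
            catalog = enr.read_gmt(config.annotation_path)

    lfc = pd.concat([
        prep.compute_lfc(mir_a, mir_b, config.pseudocount),
        prep.compute_lfc(gene_a, gene_b, config.pseudocount),
    ])

    res_a = _analyze_condition(config.condition_a, mir_a, gene_a, lfc, catalog, config)
    res_b = _analyze_condition(config.condition_b, mir_b, gene_b, lfc, catalog, config)
    comparison = compare_summaries(
        res_a.summary, res_b.summary, config.condition_a, config.condition_b
    )

    result = PipelineResult(
        config=config,
        condition_a=res_a,
        condition_b=res_b,
        lfc=lfc,
        comparison=comparison,
        truth=truth,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_condition(res_a, out / f"condition_{config.condition_a}")
        _write_condition(res_b, out / f"condition_{config.condition_b}")
        comparison.to_csv(out / "comparison.tsv", sep="\t")
        prep.write_lfc(lfc, out / "lfc.tsv")
        if truth is not None:
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(truth.to_json_dict(), fh, indent=2)
                fh.write("\n")
        if catalog is not None:
            catalog.write_gmt(out / "annotation.gmt")
        with open(out / "provenance.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("bundle written to %s", out)
    return result
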