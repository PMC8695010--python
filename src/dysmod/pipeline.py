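"""End-to-end orchestration: simulate → normalize/DE → modules → enrichment → pivots.

Each stage writes its result tables under the output directory, stamped with
a hash of the configuration that produced them; a JSON manifest records the
config snapshot and per-stage record counts. All randomness flows from the
single configured seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, de, enrich, io, network, pivots
from .datatypes import CASE, ExpressionMatrix, ModulePartition
from .simulate import SimulationConfig, generate_expression, generate_gene_sets, generate_interaction_set

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serializable to/from YAML."""

    outdir: str = "dysmod_out"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_de: bool = True
    run_modules: bool = True
    run_enrichment: bool = True
    run_pivots: bool = True
    # external inputs (used when simulate=False)
    expression_path: str | None = None
    labels_path: str | None = None
    gmt_paths: dict = field(default_factory=dict)       # category -> path
    interactions_path: str | None = None
    # simulation
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # preprocessing / DE
    normalize: bool = True
    background_offset: float = 0.0
    de_p_cutoff: float = 0.01
    # coexpression
    coexpression_samples: str = "all"   # "all" | "case"
    powers: tuple = network.DEFAULT_POWERS
    r2_cut: float = 0.85
    signed: bool = False
    min_module_size: int = 30
    cut_height: float = 0.99
    eigengene_cor_cut: float = 0.5
    hub_criterion: str = "kme"          # "kme" | "connectivity"
    # enrichment: category -> (p_cut, q_cut); GO-style 0.01/0.01, KEGG-style 0.05/0.2
    enrichment_cutoffs: dict = field(
        default_factory=lambda: {"GO": (0.01, 0.01), "KEGG": (0.05, 0.2), "simulated": (0.01, 0.01)}
    )
    enrichment_universe: str = "annotated"
    # pivots
    score_min: float = 0.5
    pivot_p_cut: float = 0.01
    pivot_min_overlap: int = 2
    pivot_background: str = "targets"   # "targets" | "all"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig.from_dict(self.sim)
        self.powers = tuple(int(b) for b in self.powers)
        for name, lo, hi in (
            ("de_p_cutoff", 0, 1), ("r2_cut", 0, 1), ("cut_height", 0, 1),
            ("eigengene_cor_cut", 0, 1), ("score_min", 0, 1), ("pivot_p_cut", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.coexpression_samples not in ("all", "case"):
            raise ValueError("coexpression_samples must be 'all' or 'case'")
        if self.pivot_background not in ("targets", "all"):
            raise ValueError("pivot_background must be 'targets' or 'all'")
        if self.hub_criterion not in ("kme", "connectivity"):
            raise ValueError("hub_criterion must be 'kme' or 'connectivity'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["powers"] = list(self.powers)
        d["enrichment_cutoffs"] = {k: list(v) for k, v in self.enrichment_cutoffs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "enrichment_cutoffs" in d:
            d["enrichment_cutoffs"] = {k: tuple(v) for k, v in d["enrichment_cutoffs"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameterization (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, stage counts, provenance."""

    config: dict
    config_hash: str
    version: str
    seed: int
    counts: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order, writing artifacts to outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"dysmod config={config.config_hash}"
    manifest = RunManifest(
        config=config.to_dict(), config_hash=config.config_hash,
        version=__version__, seed=config.seed, started=time.time(),
    )
    truth = None
    sets_by_category: dict = {}
    interactions = None

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            log.info("simulating: %d genes, %d+%d samples, %d planted modules",
                     sim_cfg.n_genes, sim_cfg.n_case, sim_cfg.n_control,
                     len(sim_cfg.module_sizes))
            matrix, truth = generate_expression(sim_cfg)
            interactions = generate_interaction_set(truth, sim_cfg)
            sets_by_category["simulated"] = generate_gene_sets(truth, sim_cfg)
            io.write_expression_table(matrix, out / "expression.tsv", out / "labels.tsv", stamp)
            io.write_interactions(interactions, out / "interactions.tsv", stamp)
            io.write_gmt(sets_by_category["simulated"], out / "gene_sets.gmt", stamp)
            io.write_json(truth.to_dict(), out / "ground_truth.json")
            manifest.counts["simulated_genes"] = matrix.n_genes
            manifest.counts["simulated_samples"] = matrix.n_samples
        else:
            matrix = io.read_expression_table(config.expression_path, config.labels_path)
            for category, path in config.gmt_paths.items():
                sets_by_category[category] = io.read_gmt(path, category=category)
            if config.interactions_path:
                interactions = io.read_interactions(config.interactions_path)

        stage = "preprocess/DE"
        if config.background_offset:
            matrix = de.subtract_background(matrix, config.background_offset)
        if config.normalize:
            matrix = de.quantile_normalize(matrix)
        if config.run_de:
            log.info("moderated t-test, DEG cutoff p < %g (case minus control)",
                     config.de_p_cutoff)
            table = de.moderated_t_test(matrix)
            degs = de.select_differential_genes(table, config.de_p_cutoff)
            io.write_table(table.rename_axis("gene"), out / "de_table.tsv", stamp, index=True)
            io.write_table(
                table.loc[degs].rename_axis("gene")[["logFC", "t", "P.Value", "adj.P.Val"]],
                out / "de_genes.tsv", stamp, index=True,
            )
            manifest.counts["de_genes"] = len(degs)

        partition: ModulePartition | None = None
        stage = "modules"
        if config.run_modules:
            sub = matrix
            if config.coexpression_samples == "case":
                sub = matrix.subset_samples(matrix.samples_in_group(CASE))
            r = network.correlation_matrix(sub)
            soft = network.pick_soft_threshold(
                sub, powers=config.powers, r2_cut=config.r2_cut, signed=config.signed, r=r
            )
            adj = network.adjacency_from_correlation(r, soft.beta, signed=config.signed)
            tom = network.topological_overlap(adj)
            partition = network.detect_modules(
                tom, min_module_size=config.min_module_size, cut_height=config.cut_height
            )
            partition = network.module_eigengenes(sub, partition)
            partition = network.hub_genes(sub, partition)
            if config.hub_criterion == "connectivity":
                partition.hub_gene = network.intramodular_hub_genes(adj, partition)
            _write_module_outputs(out, partition, soft, stamp, config)
            manifest.counts["modules"] = len(partition.modules)
            manifest.counts["gray_genes"] = partition.n_gray
            manifest.counts["hub_genes"] = len(partition.hub_gene)
            manifest.counts["soft_threshold_beta"] = soft.beta

        stage = "enrichment"
        if config.run_enrichment and partition is not None and sets_by_category:
            frames = []
            for category, sets in sorted(sets_by_category.items()):
                p_cut, q_cut = config.enrichment_cutoffs.get(category, (0.01, 0.01))
                log.info("enrichment for %s at p < %g, q < %g", category, p_cut, q_cut)
                frames.append(
                    enrich.enrich_modules(
                        partition, sets, p_cut=p_cut, q_cut=q_cut,
                        universe=config.enrichment_universe,
                    )
                )
            import pandas as pd

            records = pd.concat(frames, ignore_index=True) if frames else None
            io.write_table(records, out / "enrichment.tsv", stamp)
            io.write_table(enrich.term_module_edges(records), out / "term_module_edges.tsv", stamp)
            manifest.counts["enriched_records"] = len(records)
            manifest.counts["enriched_terms_per_module"] = {
                int(m): int(c) for m, c in records.groupby("module").size().items()
            }

        stage = "pivots"
        if config.run_pivots and partition is not None and interactions is not None:
            log.info("pivot scan: score >= %g, p < %g, >= %d targets in module",
                     config.score_min, config.pivot_p_cut, config.pivot_min_overlap)
            filtered = pivots.filter_by_score(interactions, config.score_min)
            background = (
                frozenset(partition.gene_ids) if config.pivot_background == "all" else None
            )
            records = pivots.scan_pivots(
                filtered, partition, background=background,
                p_cut=config.pivot_p_cut, min_overlap=config.pivot_min_overlap,
            )
            core = pivots.rank_core_pivots(records)
            g = pivots.regulator_module_network(records)
            io.write_table(records, out / "pivots.tsv", stamp)
            io.write_table(core, out / "core_pivots.tsv", stamp)
            io.write_edge_list(g, out / "pivot_network.tsv", stamp)
            io.write_graphml(g, out / "pivot_network.graphml")
            sig = records[records["significant"]]
            manifest.counts["pivot_records"] = len(records)
            manifest.counts["significant_pivot_pairs"] = int(len(sig))
            manifest.counts["significant_regulators"] = int(sig["regulator"].nunique())
            manifest.counts["core_pivots"] = len(core)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest.finished = time.time()
    io.write_json(manifest.to_dict(), out / "manifest.json")
    config.to_yaml(out / "config.yaml")
    return manifest


def _write_module_outputs(out: Path, partition, soft, stamp: str, config) -> None:
    import pandas as pd

    io.write_table(
        partition.module_of_gene.rename("module").rename_axis("gene").reset_index(),
        out / "modules.tsv", stamp,
    )
    io.write_table(
        partition.eigengenes.rename_axis("module"), out / "eigengenes.tsv", stamp, index=True
    )
    hubs = pd.DataFrame(
        [(m, g, partition.variance_explained.get(m)) for m, g in sorted(partition.hub_gene.items())],
        columns=["module", "hub_gene", "variance_explained"],
    )
    io.write_table(hubs, out / "hub_genes.tsv", stamp)
    diag = pd.DataFrame(
        {
            "power": list(soft.fit_r2_by_power),
            "fit_r2": list(soft.fit_r2_by_power.values()),
            "mean_connectivity": [soft.mean_connectivity_by_power[b] for b in soft.fit_r2_by_power],
        }
    )
    io.write_table(diag, out / "soft_threshold.tsv", stamp)
    if len(partition.modules) >= 2:
        edges = network.module_relationship_network(partition, config.eigengene_cor_cut)
        io.write_table(edges, out / "module_network.tsv", stamp)
        import networkx as nx

        g = nx.Graph()
        for row in edges.itertuples(index=False):
            g.add_edge(f"module:{row.module_a}", f"module:{row.module_b}", weight=float(row.cor))
        io.write_graphml(g, out / "module_network.graphml")
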