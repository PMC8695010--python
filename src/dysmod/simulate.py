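"""Synthetic expression, interaction and annotation generator with planted truth.

The generator emulates the shape of a case/control microarray study of
apoptosis-related genes: block-correlated coexpression modules arise from a
one-factor-per-module latent model, a planted subset of genes carries an
additive case-vs-control shift, regulators (ncRNA/TF) have target sets
enriched in a home module, and annotation terms are enriched in a home module.
Every downstream stage can therefore be scored against known ground truth
without any external download.

Model
-----
For module m and sample s a latent factor ``f_{m,s} ~ N(0,1)`` is drawn once;
gene g planted in m has expression ``x_{g,s} = loading * f_{m,s} + eps`` with
``eps ~ N(0, noise_sd^2)``. Background genes are pure noise. The population
within-module correlation is ``loading^2 / (loading^2 + noise_sd^2)``.
Differential genes get ``+de_effect`` added in case samples only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, NCRNA, TF, ExpressionMatrix, GeneSetCollection, InteractionSet

#: Default planted module sizes: 11 modules spanning 60-400 genes, mirroring a
#: ~4600-gene apoptosis panel partitioned into 11 coexpression modules.
DEFAULT_MODULE_SIZES = (400, 350, 320, 280, 250, 220, 180, 150, 120, 90, 60)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated study shape
    (4571 genes, 90 cases + 90 controls, 11 planted modules)."""

    n_genes: int = 4571
    n_case: int = 90
    n_control: int = 90
    module_sizes: tuple = DEFAULT_MODULE_SIZES
    loading: float = 0.8
    noise_sd: float = 0.6
    de_fraction: float = 0.1
    de_effect: float = 1.0
    n_regulators: int = 6
    targets_per_regulator: int = 10
    in_module_fraction: float = 0.8
    n_terms: int = 11
    term_size: int = 50
    term_in_module_fraction: float = 0.8
    seed: int = 0
    # optional structure toggles
    shared_factor_pairs: tuple = ()   # ((i, j), ...): module j reuses module i's factor
    core_modules: int = 0             # >0 adds one regulator spanning that many modules
    score_jitter: int = 0             # extra sub-0.5-score ncRNA edges, to exercise filtering

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if not 0 < self.loading <= 1:
            raise ValueError("loading must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("de_fraction", "in_module_fraction", "term_in_module_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_genes, self.n_case, self.n_control, self.targets_per_regulator,
               self.term_size) <= 0:
            raise ValueError("counts must be positive")
        if self.n_regulators < 0 or self.n_terms < 0:
            raise ValueError("n_regulators and n_terms must be nonnegative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["shared_factor_pairs"] = [list(p) for p in self.shared_factor_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "module_sizes" in d:
            d["module_sizes"] = tuple(d["module_sizes"])
        if "shared_factor_pairs" in d:
            d["shared_factor_pairs"] = tuple(tuple(p) for p in d["shared_factor_pairs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure underlying one simulated dataset."""

    module_of_gene: dict = field(default_factory=dict)   # gene -> int module or "background"
    de_genes: frozenset = frozenset()
    pivot_regulators: dict = field(default_factory=dict)  # regulator -> home module
    core_regulators: dict = field(default_factory=dict)   # regulator -> list of home modules
    enriched_terms: dict = field(default_factory=dict)    # term -> home module
    latent_factors: pd.DataFrame | None = None            # module x sample

    def genes_in_module(self, module: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == module]

    def to_dict(self) -> dict:
        return {
            "module_of_gene": dict(self.module_of_gene),
            "de_genes": sorted(self.de_genes),
            "pivot_regulators": dict(self.pivot_regulators),
            "core_regulators": {k: list(v) for k, v in self.core_regulators.items()},
            "enriched_terms": dict(self.enriched_terms),
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a gene-by-sample matrix from the planted latent-factor model.

    Returns the expression matrix (cases first, then controls) together with
    the ground truth. Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_samples = config.n_case + config.n_control
    genes = _gene_ids(n)
    samples = [f"case{i:03d}" for i in range(1, config.n_case + 1)] + [
        f"ctrl{i:03d}" for i in range(1, config.n_control + 1)
    ]
    groups = pd.Series(
        [CASE] * config.n_case + [CONTROL] * config.n_control, index=samples, name="group"
    )

    n_modules = len(config.module_sizes)
    factors = rng.standard_normal((n_modules, n_samples))
    for i, j in config.shared_factor_pairs:
        factors[j - 1] = factors[i - 1]

    x = rng.normal(0.0, config.noise_sd, size=(n, n_samples))
    module_of_gene: dict = {}
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        block = slice(pos, pos + size)
        x[block] += config.loading * factors[m - 1]
        for g in genes[block]:
            module_of_gene[g] = m
        pos += size
    for g in genes[pos:]:
        module_of_gene[g] = "background"

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    x[de_idx, : config.n_case] += config.de_effect
    de_genes = frozenset(genes[i] for i in de_idx)

    truth = GroundTruth(
        module_of_gene=module_of_gene,
        de_genes=de_genes,
        latent_factors=pd.DataFrame(
            factors, index=list(range(1, n_modules + 1)), columns=samples
        ),
    )
    matrix = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)
    return matrix, truth


def _draw_targets(rng, home_genes, pool, k_in: int, k_out: int) -> list[str]:
    """k_in draws from the home module, then k_out from the remaining pool."""
    t_in = list(rng.choice(home_genes, size=k_in, replace=False)) if k_in else []
    if k_out:
        rest = np.setdiff1d(pool, np.array(t_in, dtype=object)) if t_in else pool
        t_out = list(rng.choice(rest, size=k_out, replace=False))
    else:
        t_out = []
    return t_in + t_out


def generate_interaction_set(truth: GroundTruth, config: SimulationConfig) -> InteractionSet:
    """Build regulator→target edges with planted module-enriched regulators.

    Planted regulators alternate ncRNA/TF type; each draws
    ``round(in_module_fraction * targets_per_regulator)`` distinct targets from
    its home module and the rest uniformly from the remaining genes (so a
    fraction of 0 degenerates to uniform sampling). An equal number of null
    regulators sample targets uniformly. ncRNA edges carry scores uniform in
    [0.5, 1]; TF edges are unscored. ``score_jitter`` adds extra low-score
    ncRNA edges so downstream score filtering has something to remove.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = np.array(sorted(truth.module_of_gene), dtype=object)
    n_modules = len(config.module_sizes)
    k = config.targets_per_regulator
    k_in = int(round(config.in_module_fraction * k))
    rows: list[tuple] = []

    def add_edges(name, typ, targets):
        for t in targets:
            score = rng.uniform(0.5, 1.0) if typ == NCRNA else np.nan
            rows.append((name, t, typ, score))

    for i in range(config.n_regulators):
        home = (i % n_modules) + 1
        home_genes = np.array(truth.genes_in_module(home), dtype=object)
        if k_in > len(home_genes):
            raise ValueError(
                f"regulator demands {k_in} in-module targets but module {home} "
                f"has only {len(home_genes)} genes"
            )
        typ = NCRNA if i % 2 == 0 else TF
        name = f"{'ncR' if typ == NCRNA else 'TF'}{i + 1:03d}"
        # out-of-module share drawn uniformly from all remaining genes, so a
        # fraction of 0 reduces to the null expectation n*K/N
        add_edges(name, typ, _draw_targets(rng, home_genes, genes, k_in, k - k_in))
        truth.pivot_regulators[name] = home

    if config.core_modules > 0:
        # the core regulator carries full single-pivot-strength evidence
        # (k_in in-module targets) in each of its home modules
        homes = list(range(1, min(config.core_modules, n_modules) + 1))
        targets: list[str] = []
        home_pool: list[str] = []
        for home in homes:
            home_genes = np.array(truth.genes_in_module(home), dtype=object)
            targets += list(rng.choice(home_genes, size=max(2, k_in), replace=False))
            home_pool += list(home_genes)
        n_out = max(0, k - k_in)
        pool = np.setdiff1d(genes, np.array(home_pool, dtype=object))
        targets += list(rng.choice(pool, size=n_out, replace=False))
        add_edges("ncRCORE", NCRNA, targets)
        truth.core_regulators["ncRCORE"] = homes

    for i in range(config.n_regulators):
        typ = NCRNA if i % 2 == 0 else TF
        name = f"null{'ncR' if typ == NCRNA else 'TF'}{i + 1:03d}"
        add_edges(name, typ, rng.choice(genes, size=k, replace=False))

    for j in range(config.score_jitter):
        target = rng.choice(genes)
        rows.append((f"lowscore{j + 1:03d}", target, NCRNA, rng.uniform(0.0, 0.5)))

    return InteractionSet(pd.DataFrame(rows, columns=["regulator", "target", "type", "score"]))


def generate_gene_sets(truth: GroundTruth, config: SimulationConfig) -> GeneSetCollection:
    """Build annotation terms, half planted (home-module enriched), half null.

    Each planted term draws ``term_in_module_fraction`` of its members from its
    home module (cycling over planted modules) and the rest from other genes;
    null terms of the same size sample uniformly from all genes.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = np.array(sorted(truth.module_of_gene), dtype=object)
    if config.term_size > len(genes):
        raise ValueError("term_size exceeds the number of genes")
    n_modules = len(config.module_sizes)
    sets: dict[str, frozenset] = {}
    for i in range(config.n_terms):
        home = (i % n_modules) + 1
        home_genes = np.array(truth.genes_in_module(home), dtype=object)
        k_in = min(int(round(config.term_in_module_fraction * config.term_size)), len(home_genes))
        other = np.setdiff1d(genes, home_genes)
        term = f"TERM{i + 1:04d}"
        sets[term] = frozenset(
            _draw_targets(rng, home_genes, other, k_in, config.term_size - k_in)
        )
        truth.enriched_terms[term] = home
    for i in range(config.n_terms):
        sets[f"NULL{i + 1:04d}"] = frozenset(
            rng.choice(genes, size=config.term_size, replace=False)
        )
    return GeneSetCollection(sets=sets, category="simulated")
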