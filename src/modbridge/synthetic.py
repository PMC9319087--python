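"""Synthetic multi-population study generator.

Emulates the statistical structure the pipeline assumes: several
populations measured on a shared gene universe, a scale-free
protein-interaction network, and one or more planted disease modules whose
member genes are shared across populations while the effect-carrying
genes differ per population — the premise that module-level analysis
transfers across ancestries even when gene-level hits do not.  Expression
is simulated directly at the imputed (GReX) level: per-gene baseline +
covariate contributions (sex, age, latent structure factors recorded as
PCs) + a case-only mean shift on each population's effect genes + Gaussian
noise.  A dosage+weights mode produces inputs for the linear GReX
predictor.  All output is fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    DosageMatrix,
    ExpressionMatrix,
    SampleTable,
    WeightDB,
    write_expression,
    write_gmt,
    write_network,
    write_sample_table,
)

__all__ = [
    "PlantedModule",
    "SimConfig",
    "StudyBundle",
    "simulate_network",
    "simulate_population",
    "simulate_study",
    "simulate_dosage_inputs",
    "BRAIN_TISSUES",
    "AD_COHORT_PRESET",
]

# GTEx brain-tissue vocabulary used for tissue labels
BRAIN_TISSUES = [
    "amygdala", "anterior_cingulate_cortex_ba24", "caudate_basal_ganglia",
    "cerebellar_hemisphere", "cerebellum", "cortex", "frontal_cortex_ba9",
    "hippocampus", "hypothalamus", "nucleus_accumbens_basal_ganglia",
    "putamen_basal_ganglia", "spinal_cord_cervical_c1", "substantia_nigra",
]

# case/control counts of the three AD cohorts the generator can emulate
# (including the heavily imbalanced African-descent cohort)
AD_COHORT_PRESET = {"White": (1266, 1279), "Afr": (85, 1136), "Hisp": (1425, 1677)}

_DEFAULT_POP_LABELS = ["Afr", "Hisp", "White"]


@dataclass
class PlantedModule:
    """A disease module planted into the simulation.

    ``size`` genes form a connected subnetwork; per population only a
    subset of them carries the case/control mean shift (``effect_size_sd``
    in units of the noise SD).  When ``effect_subsets`` is None, each
    population gets a sliding window of ``effect_subset_size`` members
    (evenly spaced starts), so populations share the module while their
    effect genes differ, with minimal overlap between adjacent windows —
    the partially overlapping association landscapes the pipeline is
    designed to bridge.
    """

    size: int = 10
    effect_size_sd: float = 0.8
    effect_subset_size: int | None = None
    effect_subsets: list[list[str]] | None = None

    def subset_size(self) -> int:
        if self.effect_subset_size is not None:
            return self.effect_subset_size
        return max(1, round(0.4 * self.size))


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults: 3 populations x (150 cases + 150 controls), 600 genes (the
    per-tissue imputable-gene scale, reduced), one planted 10-gene module
    with a 0.8-SD case shift on population-specific member subsets,
    scale-free network with mean degree ~4, unit noise.
    """

    n_populations: int = 3
    n_cases: int | list[int] = 150
    n_controls: int | list[int] = 150
    n_genes: int = 600
    n_tissues: int = 1
    mean_degree: float = 4.0
    planted: list[PlantedModule] = field(default_factory=lambda: [PlantedModule()])
    sex_effect_sd: float = 0.1
    age_effect_sd: float = 0.1
    n_pc_factors: int = 4
    pc_effect_sd: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 1 or self.n_tissues > len(BRAIN_TISSUES):
            raise ValueError(f"n_tissues must be in [1, {len(BRAIN_TISSUES)}]")
        for pm in self.planted:
            if pm.size > self.n_genes:
                raise ValueError("planted module larger than gene universe")

    def pop_labels(self) -> list[str]:
        if self.n_populations == 3:
            return list(_DEFAULT_POP_LABELS)
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def cases_controls(self, pop_index: int) -> tuple[int, int]:
        nc = self.n_cases[pop_index] if isinstance(self.n_cases, list) else self.n_cases
        nk = self.n_controls[pop_index] if isinstance(self.n_controls, list) else self.n_controls
        return int(nc), int(nk)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


@dataclass
class StudyBundle:
    """Everything one simulated study produces, plus the ground truth."""

    graph: nx.Graph
    expression: dict[str, ExpressionMatrix]
    samples: dict[str, SampleTable]
    truth: dict
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_network(self.graph, outdir / "network.tsv")
        for pop in self.expression:
            write_expression(self.expression[pop], outdir / f"expression_{pop}.tsv")
            write_sample_table(self.samples[pop], outdir / f"samples_{pop}.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_network(config: SimConfig, members_by_module: list[list[str]] | None = None,
                     rng: np.random.Generator | None = None) -> nx.Graph:
    """Scale-free (preferential-attachment) network over the gene universe.

    Planted-module members are additionally wired into a connected,
    fairly dense subgraph (a random spanning path plus extra random
    within-module edges), so each planted module forms the kind of
    interconnected neighborhood the greedy search can traverse.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    m = max(1, int(round(config.mean_degree / 2.0)))
    ba = nx.barabasi_albert_graph(config.n_genes, m, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(ba, dict(enumerate(genes)))
    if members_by_module:
        for members in members_by_module:
            if len(members) > config.n_genes:
                raise ValueError("cannot wire planted module: too few genes")
            shuffled = list(members)
            rng.shuffle(shuffled)
            for a, b in zip(shuffled, shuffled[1:]):  # random spanning path
                graph.add_edge(a, b)
            for i in range(len(members)):  # densify within the module
                for j in range(i + 1, len(members)):
                    if rng.random() < 0.3:
                        graph.add_edge(members[i], members[j])
    return graph


def _sliding_windows(members: list[str], n_parts: int, width: int) -> list[list[str]]:
    """Evenly spaced windows of *width* members, one per population."""
    n = len(members)
    width = min(width, n)
    if n_parts == 1:
        return [members[:width]]
    span = n - width
    starts = [round(i * span / (n_parts - 1)) for i in range(n_parts)]
    return [members[s:s + width] for s in starts]


def simulate_population(
    config: SimConfig,
    population_index: int,
    effect_genes: dict[str, float] | None = None,
    tissue: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Simulate one population's expression matrix and sample table.

    *effect_genes* maps gene id -> case-only mean shift (in noise-SD
    units); when None the population has no planted signal.
    """
    rng = rng or np.random.default_rng([config.seed, 7, population_index])
    pop = config.pop_labels()[population_index]
    tissue = tissue or BRAIN_TISSUES[0]
    n_cases, n_controls = config.cases_controls(population_index)
    n = n_cases + n_controls
    genes = _gene_ids(config.n_genes)

    phenotype = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    sex = rng.integers(0, 2, n)
    age = np.clip(rng.normal(75.0, 8.0, n), 40.0, None)
    factors = rng.normal(size=(n, config.n_pc_factors))

    baseline = rng.normal(size=(config.n_genes, 1))
    sex_load = rng.normal(0.0, config.sex_effect_sd, size=(config.n_genes, 1))
    age_load = rng.normal(0.0, config.age_effect_sd, size=(config.n_genes, 1))
    pc_load = rng.normal(0.0, config.pc_effect_sd,
                         size=(config.n_genes, config.n_pc_factors))
    age_std = (age - 75.0) / 8.0

    values = (
        baseline
        + sex_load * sex[None, :]
        + age_load * age_std[None, :]
        + pc_load @ factors.T
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    )
    if effect_genes:
        gidx = {g: i for i, g in enumerate(genes)}
        for g, shift in effect_genes.items():
            values[gidx[g], phenotype == 1] += shift * config.noise_sd

    sample_ids = [f"{pop}_s{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(genes, sample_ids, values, population=pop, tissue=tissue)
    frame = pd.DataFrame(
        {
            "phenotype": phenotype, "sex": sex, "age": age,
            **{f"pc_{j + 1}": factors[:, j] for j in range(config.n_pc_factors)},
            "population": pop,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return expr, SampleTable(frame)


def simulate_study(config: SimConfig | None = None) -> StudyBundle:
    """Full fixture bundle: network + per-population data + ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng([config.seed, 1])
    genes = _gene_ids(config.n_genes)
    pops = config.pop_labels()

    members_by_module, truth_modules = [], []
    taken: set[str] = set()
    for pm in config.planted:
        free = [g for g in genes if g not in taken]
        members = sorted(str(g) for g in rng.choice(free, size=pm.size, replace=False))
        taken.update(members)
        members_by_module.append(members)
        if pm.effect_subsets is not None:
            subsets = [list(s) for s in pm.effect_subsets]
            if len(subsets) != config.n_populations:
                raise ValueError("effect_subsets must list one subset per population")
            for s in subsets:
                if not set(s) <= set(members):
                    raise ValueError("effect subset not contained in module members")
        else:
            subsets = _sliding_windows(members, config.n_populations, pm.subset_size())
        truth_modules.append({
            "members": members,
            "effect_size_sd": pm.effect_size_sd,
            "effect_genes": {pops[i]: sorted(subsets[i]) for i in range(len(pops))},
        })

    graph = simulate_network(config, members_by_module, np.random.default_rng([config.seed, 2]))

    expression, samples = {}, {}
    tissue = BRAIN_TISSUES[0]
    for i, pop in enumerate(pops):
        effect: dict[str, float] = {}
        for pm, tm in zip(config.planted, truth_modules):
            for g in tm["effect_genes"][pop]:
                effect[g] = pm.effect_size_sd
        expr, table = simulate_population(
            config, i, effect, tissue, np.random.default_rng([config.seed, 7, i]),
        )
        expression[pop] = expr
        samples[pop] = table

    truth = {"modules": truth_modules, "seed": config.seed, "tissue": tissue}
    return StudyBundle(graph, expression, samples, truth, config)


def simulate_dosage_inputs(
    n_genes: int = 20,
    n_variants_per_gene: int = 3,
    n_samples: int = 50,
    seed: int = 0,
) -> tuple[DosageMatrix, WeightDB]:
    """Toy dosage matrix + weight model feeding the linear GReX predictor."""
    rng = np.random.default_rng([seed, 11])
    genes = _gene_ids(n_genes)
    variants, weights = [], {}
    for g in genes:
        vs = [f"{g}_v{j}" for j in range(n_variants_per_gene)]
        variants.extend(vs)
        weights[g] = [(v, float(rng.normal(0, 0.5))) for v in vs]
    maf = rng.uniform(0.05, 0.5, len(variants))
    dos = rng.binomial(2, maf[:, None], size=(len(variants), n_samples)).astype(float)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    return DosageMatrix(variants, samples, dos), WeightDB(weights)
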