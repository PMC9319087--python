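"""Cross-population bridging of discovered gene modules.

Each population in turn acts as the discovery cohort: its node weights
drive the dense module search.  A second population re-scores the
discovered modules with its own weights (evaluation), and modules that
validate there are combined with the third population by an equal-weight
Stouffer sum of normalized scores, assessed against a matched permutation
null.  Modules surviving all three cohorts are "shared across
populations"; their member-gene unions feed the overlap (Venn) report and
the hypergeometric pathway enrichment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, ModuleRecord
from .module_search import (
    NullDistribution,
    SearchConfig,
    build_null,
    dense_module_search,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvalScore",
    "CrossPopResult",
    "OverlapReport",
    "evaluate_modules",
    "combine_third_population",
    "run_rotation",
    "overlap_report",
    "consensus_shared_modules",
    "enrich_hypergeometric",
]


@dataclass
class EvalScore:
    """Re-score of a discovery module in another cohort.

    ``covered`` counts module members carrying a weight in that cohort;
    scoring uses only those (size k').  Modules below the coverage
    threshold are non-evaluable.
    """

    z_m: float = float("nan")
    z_n: float = float("nan")
    perm_p: float = float("nan")
    covered: int = 0
    evaluable: bool = False


@dataclass
class CrossPopResult:
    """One discovery module with its cross-cohort scores and decisions."""

    module: ModuleRecord
    discovery_population: str
    eval_scores: dict[str, EvalScore] = field(default_factory=dict)
    validated: dict[str, bool] = field(default_factory=dict)
    combined_score: float = float("nan")
    combined_p: float = float("nan")
    shared: bool = False

    def __post_init__(self) -> None:
        if self.discovery_population in self.eval_scores:
            raise ValueError("evaluation population equals discovery population")


def evaluate_modules(
    discovery_modules: list[ModuleRecord],
    eval_weights,
    eval_population: str,
    config: SearchConfig | None = None,
    coverage_threshold: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, EvalScore], NullDistribution | None]:
    """Re-score discovery modules with evaluation-cohort weights.

    For each module, members covered by the evaluation weights (count k')
    are scored Z_m' = sum(z')/sqrt(k') and normalized against a size-k'
    random-set null built from the evaluation weights.  Modules whose
    coverage falls below *coverage_threshold* are marked non-evaluable
    rather than silently scored on one or two genes.
    """
    config = config or SearchConfig()
    rng = rng or np.random.default_rng(config.seed)
    covered_sets = {}
    for m in discovery_modules:
        cov = sorted(g for g in m.members if g in eval_weights)
        covered_sets[m.module_id] = cov
    sizes = {len(c) for c in covered_sets.values() if c}
    null = build_null(eval_weights, sizes, config.n_perm, rng) if sizes else None
    scores: dict[str, EvalScore] = {}
    n_skip = 0
    for m in discovery_modules:
        cov = covered_sets[m.module_id]
        if not cov or len(cov) / m.k < coverage_threshold:
            scores[m.module_id] = EvalScore(covered=len(cov), evaluable=False)
            n_skip += 1
            continue
        z_m = sum(eval_weights[g] for g in cov) / math.sqrt(len(cov))
        scores[m.module_id] = EvalScore(
            z_m=z_m,
            z_n=null.normalize(z_m, len(cov)),
            perm_p=null.empirical_p(z_m, len(cov)),
            covered=len(cov),
            evaluable=True,
        )
    if n_skip:
        logger.warning(
            "evaluate_modules[%s]: %d/%d module(s) non-evaluable (coverage < %g)",
            eval_population, n_skip, len(discovery_modules), coverage_threshold,
        )
    if n_skip == len(discovery_modules):
        logger.warning("evaluate_modules[%s]: zero evaluable modules", eval_population)
    return scores, null


def combine_third_population(
    result: CrossPopResult,
    third_weights,
    third_population: str,
    discovery_null: NullDistribution,
    eval_null: NullDistribution,
    eval_population: str,
    config: SearchConfig | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> CrossPopResult:
    """Stouffer-combine discovery, evaluation and third-population scores.

    combined = (Z_N_disc + Z_N_eval + Z_N_third)/sqrt(3), assessed against
    the matched combined null: the per-draw Stouffer sum of each cohort's
    normalized size-matched null draws.  The module counts as shared
    across the three populations iff the combined empirical p < *alpha*.

    Requires the module to have validated in the evaluation cohort
    (perm_p_eval < alpha); otherwise the result is returned untouched.
    """
    config = config or SearchConfig()
    rng = rng or np.random.default_rng(config.seed)
    es_eval = result.eval_scores.get(eval_population)
    if es_eval is None or not result.validated.get(eval_population, False):
        return result
    third_scores, third_null = evaluate_modules(
        [result.module], third_weights, third_population, config, rng=rng,
    )
    es_third = third_scores[result.module.module_id]
    result.eval_scores[third_population] = es_third
    result.validated[third_population] = bool(
        es_third.evaluable and es_third.perm_p < alpha
    )
    if not es_third.evaluable:
        return result
    z = np.array([result.module.normalized_score, es_eval.z_n, es_third.z_n])
    result.combined_score = float(z.sum() / math.sqrt(3))
    null_combined = (
        discovery_null.normalized_draws(result.module.k)
        + eval_null.normalized_draws(es_eval.covered)
        + third_null.normalized_draws(es_third.covered)
    ) / math.sqrt(3)
    result.combined_p = (
        1.0 + int((null_combined >= result.combined_score).sum())
    ) / (len(null_combined) + 1.0)
    result.shared = result.combined_p < alpha
    return result


def run_rotation(
    weights_by_pop: dict[str, dict],
    graph: nx.Graph,
    config: SearchConfig | None = None,
    alpha: float = 0.05,
    coverage_threshold: float = 0.5,
    tissue: str = "",
) -> dict[str, list[CrossPopResult]]:
    """Full discovery-role rotation over the populations.

    Each population serves once as discovery; of the remaining populations
    (lexicographic order) the first is the evaluation cohort and the
    second the third (combination) population.  With only two populations
    the rotation degrades to dual-cohort mode (evaluation only, no
    combination), with a logged notice.
    """
    config = config or SearchConfig()
    pops = sorted(weights_by_pop)
    if len(pops) < 2:
        raise ValueError("rotation needs >=2 populations")
    if len(pops) == 2:
        logger.warning("run_rotation: 2 populations; dual-cohort mode, no triple combination")
    results: dict[str, list[CrossPopResult]] = {}
    for i, disc in enumerate(pops):
        others = [p for p in pops if p != disc]
        eval_pop = others[0]
        third_pop = others[1] if len(others) > 1 else None
        rng = np.random.default_rng([config.seed, i])
        cfg = SearchConfig(config.r, config.d, config.n_perm, config.top_fraction,
                           seed=int(rng.integers(2**31)))
        modules, disc_null = dense_module_search(
            graph, weights_by_pop[disc], cfg, population=disc, tissue=tissue,
        )
        eval_scores, eval_null = evaluate_modules(
            modules, weights_by_pop[eval_pop], eval_pop, cfg,
            coverage_threshold, rng,
        )
        pop_results = []
        for m in modules:
            es = eval_scores[m.module_id]
            res = CrossPopResult(
                module=m, discovery_population=disc,
                eval_scores={eval_pop: es},
                validated={eval_pop: bool(es.evaluable and es.perm_p < alpha)},
            )
            if third_pop is not None and res.validated[eval_pop]:
                res = combine_third_population(
                    res, weights_by_pop[third_pop], third_pop,
                    disc_null, eval_null, eval_pop, cfg, alpha, rng,
                )
            pop_results.append(res)
        results[disc] = pop_results
    return results


def consensus_shared_modules(
    results: dict[str, list[CrossPopResult]],
) -> list[frozenset]:
    """Merge triple-shared modules across discovery roles into consensus modules.

    Each discovery population reports the planted signal through its own
    effect genes, so shared modules from different rotations typically
    overlap only partially.  Modules flagged ``shared`` are merged by
    single-linkage on member overlap (two modules join one consensus
    module iff they share at least one gene, transitively); the merged
    member unions are returned largest-first.
    """
    shared = [r.module.members for rl in results.values() for r in rl if r.shared]
    merged: list[set] = []
    for members in shared:
        hits = [c for c in merged if c & members]
        union = set(members).union(*hits) if hits else set(members)
        merged = [c for c in merged if not (c & members)]
        merged.append(union)
    return sorted((frozenset(c) for c in merged), key=lambda c: (-len(c), sorted(c)))


@dataclass
class OverlapReport:
    """Venn-style overlap counts between populations' validated modules.

    Keys of the count dicts are sorted population tuples; gene overlaps
    intersect the unions of validated-module members per population.
    """

    module_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    gene_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    shared_genes: dict[tuple[str, ...], list[str]] = field(default_factory=dict)
    mode: str = "exact"


def _module_sets(results: list[CrossPopResult]) -> set[frozenset]:
    return {r.module.members for r in results}


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def overlap_report(
    validated: dict[str, list[CrossPopResult]],
    mode: str = "exact",
    jaccard_threshold: float = 0.8,
) -> OverlapReport:
    """Module- and gene-level overlaps across populations.

    mode="exact": a module is shared by a population tuple iff the same
    member set appears in all of them.  mode="jaccard": a module in the
    first population counts as shared iff every other population has a
    module with Jaccard >= *jaccard_threshold* against it.
    Gene-level overlaps are intersections of per-population unions of
    validated-module members, so inclusion-exclusion identities hold
    exactly.
    """
    if len(validated) < 2:
        raise ValueError("overlap report needs >=2 populations")
    if mode not in ("exact", "jaccard"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    report = OverlapReport(mode=mode)
    gene_unions = {
        pop: set().union(*(r.module.members for r in res)) if res else set()
        for pop, res in validated.items()
    }
    pops = sorted(validated)
    for size in range(2, len(pops) + 1):
        for combo in itertools.combinations(pops, size):
            if mode == "exact":
                shared = set.intersection(*(set(_module_sets(validated[p])) for p in combo))
                n_mod = len(shared)
            else:
                first, *rest = combo
                n_mod = sum(
                    all(
                        any(_jaccard(m, other) >= jaccard_threshold
                            for other in _module_sets(validated[p]))
                        for p in rest
                    )
                    for m in _module_sets(validated[first])
                )
            genes = set.intersection(*(gene_unions[p] for p in combo))
            report.module_counts[combo] = n_mod
            report.gene_counts[combo] = len(genes)
            report.shared_genes[combo] = sorted(genes)
    return report


def enrich_hypergeometric(
    gene_list,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of *gene_list* in each set.

    The upper-tail p is P(X >= overlap) with X hypergeometric over
    *universe*; q-values are Benjamini-Hochberg.  Rows sorted ascending
    by p.
    """
    universe = set(universe)
    gene_list = [g for g in dict.fromkeys(gene_list)]
    if not universe:
        raise ValueError("empty universe")
    if not gene_list:
        raise ValueError("empty gene list")
    outside = [g for g in gene_list if g not in universe]
    if outside:
        raise ValueError(f"gene list members outside universe: {outside[:5]}")
    M, N = len(universe), len(gene_list)
    rows = []
    for name, (desc, members) in collection:
        in_universe = [g for g in members if g in universe]
        n = len(in_universe)
        if n == 0:
            continue
        x = len(set(in_universe) & set(gene_list))
        p = float(stats.hypergeom.sf(x - 1, M, n, N))
        rows.append({
            "set_name": name, "description": desc, "set_size": n,
            "overlap": x, "p_value": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
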