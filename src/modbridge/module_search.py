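"""Dense gene-module search on a protein-interaction network.

Differential-expression p-values become per-gene node weights
z = Phi^-1(1 - p); a module's score is Z_m = sum(z_i)/sqrt(k).  From every
seed gene a module is grown greedily: among candidate genes within
shortest-path distance d of the current module, the one maximizing the new
score is added, but only if it improves the score by more than a factor
(1 + r); the search stops when no candidate qualifies.  Each module is then
normalized against a permutation null of size-matched random gene sets
(weight-label permutation): Z_N = (Z_m - mu_k)/sigma_k, with an add-one
empirical p-value.  These are the published dense-module-search (dmGWAS)
defaults; r, d and the permutation count are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ModuleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "NullDistribution",
    "pvals_to_weights",
    "module_score",
    "grow_module",
    "permute_and_normalize",
    "select_top_modules",
    "dense_module_search",
]

P_CLIP = 1e-16  # p-values clipped to [P_CLIP, 1 - P_CLIP] before Phi^-1


@dataclass
class SearchConfig:
    """Knobs of the greedy search and its permutation null.

    r : minimum relative score improvement to accept an expansion
        (Z_new > Z_old * (1 + r)).
    d : candidate neighborhood distance (graph hops from the module).
    n_perm : permutation draws per module size.
    top_fraction : fraction of seed modules retained as significant.
    seed : RNG seed for the permutation null.
    """

    r: float = 0.1
    d: int = 1
    n_perm: int = 1000
    top_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def pvals_to_weights(de: pd.DataFrame, p_column: str = "p_value") -> dict[str, float]:
    """Map per-gene p-values to node weights z = Phi^-1(1 - p).

    p is clipped to [1e-16, 1 - 1e-16] so weights stay finite; genes with
    missing p-values are excluded (logged).  Small p -> large positive z
    regardless of effect direction (one-tailed weighting in weight space).
    """
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    p = de[p_column]
    ok = p.notna()
    if not ok.all():
        logger.info("pvals_to_weights: excluded %d gene(s) without p-value", (~ok).sum())
    p = p[ok].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    # clip in z-space: equivalent to clipping p to [eps, 1-eps] but exact
    # (1 - 1e-16 is not representable in double precision)
    z_max = stats.norm.isf(P_CLIP)
    z = np.clip(stats.norm.isf(p), -z_max, z_max)
    return dict(zip(de.index[ok], z))


def module_score(members, weights) -> float:
    """Z_m = sum of member weights / sqrt(k)."""
    members = list(members)
    if not members:
        raise ValueError("empty module")
    try:
        total = sum(weights[g] for g in members)
    except KeyError as exc:
        raise ValueError(f"module member without weight: {exc.args[0]!r}") from exc
    return total / math.sqrt(len(members))


def _distances(graph: nx.Graph, members: set[str], d: int) -> dict[str, int]:
    """Shortest-path distance (<= d) from the module for nearby genes."""
    dist = {m: 0 for m in members}
    frontier = set(members)
    for step in range(1, d + 1):
        nxt = set()
        for node in frontier:
            nxt.update(graph.neighbors(node))
        nxt -= dist.keys()
        for node in nxt:
            dist[node] = step
        frontier = nxt
        if not frontier:
            break
    return dist


def _linker_path(graph: nx.Graph, dist: dict[str, int], candidate: str, weights) -> list[str]:
    """Candidate plus the weighted genes linking it back to the module.

    Walks one shortest path toward the module, taking at each level the
    lexicographically smallest weighted neighbor (deterministic).
    """
    path = [candidate]
    cur = candidate
    for level in range(dist[candidate] - 1, 0, -1):
        nxt = min(
            n for n in graph.neighbors(cur)
            if dist.get(n) == level and n in weights
        )
        path.append(nxt)
        cur = nxt
    return path


def grow_module(
    seed_gene: str,
    graph: nx.Graph,
    weights,
    config: SearchConfig | None = None,
    population: str = "",
    tissue: str = "",
    return_trace: bool = False,
):
    """Greedy expansion from one seed gene.

    At each step the candidate (within distance ``config.d``, carrying a
    weight) that maximizes the new module score is added if the new score
    strictly exceeds the old one times (1 + r).  A candidate beyond
    distance 1 brings the weighted genes on one shortest path back to the
    module with it (lexicographically smallest path), so members always
    induce a connected subgraph; its score is computed over that whole
    addition.  Ties are broken by lexicographic gene id, making runs
    reproducible.

    Returns a ModuleRecord (raw score only; normalization happens in
    :func:`permute_and_normalize`), plus the per-step growth trace of
    ``(added_gene, score_after)`` tuples when *return_trace* is set.
    """
    config = config or SearchConfig()
    if seed_gene not in graph:
        raise ValueError(f"seed {seed_gene!r} not in network")
    if seed_gene not in weights:
        raise ValueError(f"seed {seed_gene!r} has no weight")
    if any(n not in weights for n in graph):
        graph = graph.subgraph([n for n in graph if n in weights])
    members = {seed_gene}
    total = weights[seed_gene]
    score = total  # k=1
    trace = [(seed_gene, score)]
    while True:
        dist = _distances(graph, members, config.d)
        cands = [c for c, lv in dist.items() if lv > 0 and c in weights]
        if not cands:
            break
        best_gene, best_path, best_score = None, None, -math.inf
        for c in sorted(cands):  # lexicographic order -> first max wins ties
            path = _linker_path(graph, dist, c, weights)
            s = (total + sum(weights[g] for g in path)) / math.sqrt(len(members) + len(path))
            if s > best_score:
                best_gene, best_path, best_score = c, path, s
        if best_score > score * (1.0 + config.r):
            members.update(best_path)
            total += sum(weights[g] for g in best_path)
            score = best_score
            trace.append((best_gene, score))
        else:
            break
    record = ModuleRecord(
        module_id=f"{population or 'pop'}:{tissue or 'tissue'}:{seed_gene}",
        seed_gene=seed_gene,
        members=frozenset(members),
        raw_score=score,
        population=population,
        tissue=tissue,
    )
    return (record, trace) if return_trace else record


@dataclass
class NullDistribution:
    """Permutation null of module scores per module size.

    ``draws[k]`` holds n_perm scores of uniformly random size-k gene sets
    drawn from the weighted genes; mu/sigma summarize each size.
    """

    draws: dict[int, np.ndarray] = field(default_factory=dict)

    def mu(self, k: int) -> float:
        return float(self.draws[k].mean())

    def sigma(self, k: int) -> float:
        s = float(self.draws[k].std(ddof=1))
        # constant null (all weights equal) -> rounding-level spread
        if s <= 1e-12 * max(1.0, abs(self.mu(k))):
            return 0.0
        return s

    def normalize(self, score: float, k: int) -> float:
        s = self.sigma(k)
        if s == 0.0:
            logger.warning("degenerate null (sigma=0) for module size %d; Z_N := 0", k)
            return 0.0
        return (score - self.mu(k)) / s

    def empirical_p(self, score: float, k: int) -> float:
        null = self.draws[k]
        return (1.0 + int((null >= score).sum())) / (len(null) + 1.0)

    def normalized_draws(self, k: int) -> np.ndarray:
        s = self.sigma(k)
        if s == 0.0:
            return np.zeros_like(self.draws[k])
        return (self.draws[k] - self.mu(k)) / s


def build_null(weights, sizes, n_perm: int, rng: np.random.Generator) -> NullDistribution:
    """Draw n_perm random size-k gene-set scores for each size in *sizes*."""
    w = np.asarray(list(weights.values()), dtype=float)
    null = NullDistribution()
    for k in sorted(set(sizes)):
        if k > w.size:
            raise ValueError(f"module size {k} exceeds number of weighted genes {w.size}")
        if k == w.size:
            null.draws[k] = np.full(n_perm, w.sum() / math.sqrt(k))
            continue
        u = rng.random((n_perm, w.size))
        idx = np.argpartition(u, k, axis=1)[:, :k]
        null.draws[k] = w[idx].sum(axis=1) / math.sqrt(k)
    return null


def permute_and_normalize(
    modules: list[ModuleRecord],
    weights,
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ModuleRecord], NullDistribution]:
    """Attach Z_N and add-one empirical p to each module.

    The null re-scores random gene sets of matching size drawn from the
    weighted genes (weight-label permutation; network topology enters only
    through the observed module, mirroring the dmGWAS normalization).
    """
    if not modules:
        raise ValueError("no modules to normalize")
    config = config or SearchConfig()
    rng = rng or np.random.default_rng(config.seed)
    null = build_null(weights, [m.k for m in modules], config.n_perm, rng)
    out = []
    for m in modules:
        out.append(ModuleRecord(
            module_id=m.module_id, seed_gene=m.seed_gene, members=m.members,
            raw_score=m.raw_score,
            normalized_score=null.normalize(m.raw_score, m.k),
            perm_p=null.empirical_p(m.raw_score, m.k),
            population=m.population, tissue=m.tissue,
        ))
    return out, null


def select_top_modules(
    modules: list[ModuleRecord],
    config: SearchConfig | None = None,
    alpha: float = 0.05,
) -> list[ModuleRecord]:
    """Rank by Z_N, keep the top fraction with perm_p below *alpha*.

    Identical member sets are deduplicated keeping the highest-Z_N
    instance; the result is invariant to input order.
    """
    config = config or SearchConfig()
    ranked = sorted(modules, key=lambda m: (-m.normalized_score, m.module_id))
    n_keep = max(1, int(len(ranked) * config.top_fraction))
    kept = [m for m in ranked[:n_keep] if m.perm_p < alpha]
    seen: dict[frozenset, ModuleRecord] = {}
    for m in kept:  # ranked order -> first instance has highest Z_N
        if m.members not in seen:
            seen[m.members] = m
    return list(seen.values())


def dense_module_search(
    graph: nx.Graph,
    weights,
    config: SearchConfig | None = None,
    population: str = "",
    tissue: str = "",
    select: bool = True,
) -> tuple[list[ModuleRecord], NullDistribution]:
    """Full search: grow from every weighted seed, normalize, select.

    Genes present in the network but absent from the weight table are
    removed from the graph before searching (scoring them would fabricate
    evidence); the count is logged.
    """
    config = config or SearchConfig()
    weighted = [n for n in graph.nodes if n in weights]
    dropped = graph.number_of_nodes() - len(weighted)
    if dropped:
        logger.info("dense_module_search: removed %d unweighted network gene(s)", dropped)
    sub = graph.subgraph(weighted)
    modules = [
        grow_module(s, sub, weights, config, population, tissue)
        for s in sorted(sub.nodes)
    ]
    if not modules:
        raise ValueError("no weighted seed genes in network")
    modules, null = permute_and_normalize(modules, weights, config)
    if select:
        modules = select_top_modules(modules, config)
    return modules, null
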