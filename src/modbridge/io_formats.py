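"""Domain types and on-disk formats for the module-discovery pipeline.

Every stage of the pipeline exchanges one of a handful of typed containers:
an imputed expression matrix (genes x samples) with population/tissue
labels, a sample covariate table, an undirected protein-interaction
network, gene-set collections (GMT), and discovered module records.  All
on-disk formats are plain text: TSV for matrices and tables, STRING-style
edge lists for the network, GMT for gene sets, TSV + JSON for modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "GeneSetCollection",
    "ModuleRecord",
    "DosageMatrix",
    "WeightDB",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_sample_table",
    "write_sample_table",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_dosages",
    "read_weight_db",
    "write_modules",
    "read_modules",
]


class ParseError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ParseError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with population and tissue labels.

    The unit every pipeline stage transforms: raw imputed (GReX)
    expression, covariate-adjusted residuals, and simulated fixtures all
    use this container.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    population: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows, :],
            self.population, self.tissue,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols],
            self.population, self.tissue,
        )


@dataclass
class SampleTable:
    """Per-sample phenotype (0=control, 1=case) and covariates.

    Wraps a DataFrame indexed by sample_id with at least a ``phenotype``
    column; ``sex``, ``age``, ``pc_1..pc_K`` and ``population`` are
    optional but used when present.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        if "phenotype" not in self.frame.columns:
            raise ParseError("sample table lacks required 'phenotype' column")
        ph = self.frame["phenotype"]
        if not ph.isin([0, 1]).all():
            bad = self.frame.index[~ph.isin([0, 1])].tolist()
            raise ParseError(f"phenotype must be 0/1; offending samples: {bad[:5]}")
        if "age" in self.frame.columns:
            age = pd.to_numeric(self.frame["age"], errors="coerce")
            if (age.dropna() < 0).any():
                raise ParseError("negative age in sample table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def phenotype(self, samples=None) -> np.ndarray:
        f = self.frame if samples is None else self.frame.loc[list(samples)]
        return f["phenotype"].to_numpy(dtype=int)

    def pc_columns(self) -> list[str]:
        cols = [c for c in self.frame.columns if c.startswith("pc_")]
        return sorted(cols, key=lambda c: int(c.split("_")[1]))


@dataclass
class GeneSetCollection:
    """Named gene sets: set_name -> (description, member list).

    Members are deduplicated preserving order; empty sets are rejected.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, members) in self.sets.items():
            if name in clean:
                raise ParseError(f"duplicate gene-set name: {name!r}")
            dedup = list(dict.fromkeys(members))
            if not dedup:
                raise ParseError(f"gene set {name!r} has no members after deduplication")
            clean[name] = (desc, dedup)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def filter_sizes(self, genes, min_size: int, max_size: int) -> "GeneSetCollection":
        """Intersect each set with *genes* and keep sizes in [min, max]."""
        universe = set(genes)
        kept, dropped = {}, 0
        for name, (desc, members) in self.sets.items():
            inter = [g for g in members if g in universe]
            if min_size <= len(inter) <= max_size:
                kept[name] = (desc, inter)
            else:
                dropped += 1
        if dropped:
            logger.info("gene-set size filter dropped %d of %d sets", dropped, len(self.sets))
        return GeneSetCollection(kept)


@dataclass
class ModuleRecord:
    """A discovered dense module: seed gene, members, scores, permutation p.

    ``raw_score`` is the module Z-score Z_m = sum(z_i)/sqrt(k);
    ``normalized_score`` Z_N = (Z_m - mu_k)/sigma_k against the size-k
    permutation null; ``perm_p`` the add-one empirical p-value.
    """

    module_id: str
    seed_gene: str
    members: frozenset[str]
    raw_score: float
    normalized_score: float = float("nan")
    perm_p: float = float("nan")
    population: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.seed_gene not in self.members:
            raise ValueError(f"seed {self.seed_gene!r} not among module members")
        if not np.isnan(self.perm_p) and not (0.0 < self.perm_p <= 1.0):
            raise ValueError(f"perm_p must lie in (0,1], got {self.perm_p}")

    @property
    def k(self) -> int:
        return len(self.members)


@dataclass
class DosageMatrix:
    """Variant x sample allele-dosage matrix, values in [0, 2]."""

    variant_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.variant_ids), len(self.sample_ids)):
            raise ValueError("dosage matrix shape mismatch")
        _check_unique(self.variant_ids, "variant id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")


@dataclass
class WeightDB:
    """Per-gene linear prediction weights: gene -> [(variant_id, weight)]."""

    weights: dict[str, list[tuple[str, float]]]

    def genes(self) -> list[str]:
        return list(self.weights)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, population: str = "", tissue: str = "") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (gene id first column, sample ids in header)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene rows: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna()][0]
                raise ParseError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                ) from exc
        raise ParseError(f"{path}: non-numeric expression values") from exc
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], values,
        population=population, tissue=tissue,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_network(path, min_confidence: float = 700.0) -> nx.Graph:
    """Read a 2- or 3-column whitespace/TSV edge list into a simple graph.

    STRING-style third column is a confidence score; edges below
    *min_confidence* are dropped.  Self-loops and duplicate edges are
    dropped (the graph is simple and undirected).  A node appearing only
    in dropped edges does not enter the graph.
    """
    graph = nx.Graph()
    n_self, n_dropped, n_lines = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and len(parts) >= 2 and parts[0].lower() in (
                    "protein1", "gene1", "node1", "source"):
                continue  # header line
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(parts)}")
            n_lines += 1
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            if len(parts) >= 3:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from exc
                if score < min_confidence:
                    n_dropped += 1
                    continue
                graph.add_edge(a, b, confidence=score)
            else:
                graph.add_edge(a, b)
    if n_lines == 0:
        raise ParseError(f"{path}: empty edge list")
    if n_self:
        logger.info("dropped %d self-loop(s) from %s", n_self, path)
    if n_dropped:
        logger.info("dropped %d edge(s) below confidence %g", n_dropped, min_confidence)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, data in sorted(graph.edges(data=True)):
            score = data.get("confidence", "")
            fh.write(f"{a}\t{b}\t{score}\n")


def read_gmt(path) -> GeneSetCollection:
    """Read GMT: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(parts)}")
            name, desc = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection:
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_dosages(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DosageMatrix(
        [str(v) for v in df.index], [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
    )


def read_weight_db(path) -> WeightDB:
    """Read a weight table TSV with columns gene, variant_id, weight."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "variant_id", "weight"):
        if col not in df.columns:
            raise ParseError(f"{path}: weight table lacks column {col!r}")
    weights: dict[str, list[tuple[str, float]]] = {}
    for gene, sub in df.groupby("gene", sort=False):
        weights[str(gene)] = list(
            zip(sub["variant_id"].astype(str), sub["weight"].astype(float))
        )
    return WeightDB(weights)


MODULE_TSV_COLUMNS = [
    "module_id", "population", "tissue", "seed", "k",
    "raw_score", "normalized_score", "perm_p", "members",
]


def write_modules(modules: list[ModuleRecord], path, config: dict | None = None) -> None:
    """Write modules as TSV (one row per module, members ';'-joined).

    If *path* ends in .json a JSON mirror with full provenance is written
    instead; otherwise both <path> (TSV) and <path stem>.json are emitted.
    """
    path = str(path)
    rows = []
    for m in modules:
        rows.append({
            "module_id": m.module_id, "population": m.population,
            "tissue": m.tissue, "seed": m.seed_gene, "k": m.k,
            "raw_score": m.raw_score, "normalized_score": m.normalized_score,
            "perm_p": m.perm_p, "members": ";".join(sorted(m.members)),
        })
    payload = {"config": config or {}, "modules": rows}
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    pd.DataFrame(rows, columns=MODULE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    with open(path.rsplit(".", 1)[0] + ".json", "w") as fh:
        json.dump(payload, fh, indent=1)


def _record_from_row(row: dict) -> ModuleRecord:
    return ModuleRecord(
        module_id=str(row["module_id"]), seed_gene=str(row["seed"]),
        members=frozenset(str(row["members"]).split(";")),
        raw_score=float(row["raw_score"]),
        normalized_score=float(row["normalized_score"]),
        perm_p=float(row["perm_p"]),
        population=str(row.get("population", "")), tissue=str(row.get("tissue", "")),
    )


def read_modules(path) -> list[ModuleRecord]:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        return [_record_from_row(r) for r in payload["modules"]]
    df = pd.read_csv(path, sep="\t")
    return [_record_from_row(r) for r in df.to_dict("records")]
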