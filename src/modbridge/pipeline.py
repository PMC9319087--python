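"""End-to-end orchestration: adjust -> differential expression -> dense
module search per population, then the full discovery-role rotation,
overlap report and optional GSVA arm, driven by one config file.

Every run writes a manifest (config hash, seeds, package versions,
per-stage row counts) so any stage can be re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cross_population import overlap_report, run_rotation
from .diffexpr import differential_expression
from .gsva import GsvaConfig, gsva_differential, gsva_scores
from .io_formats import (
    read_expression,
    read_gmt,
    read_network,
    read_sample_table,
    write_modules,
)
from .module_search import SearchConfig, pvals_to_weights
from .preprocess import DEFAULT_COVARIATES, adjust_covariates, compute_pcs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and parameters for one full run.

    ``populations`` maps population label -> {"expression": path,
    "samples": path}.  When the sample table lacks pc_ columns they are
    computed from expression (``n_pcs`` of them) and labelled as
    expression-derived in the manifest.
    """

    populations: dict[str, dict[str, str]]
    network: str
    out_dir: str
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    n_pcs: int = 4
    min_confidence: float = 700.0
    search: SearchConfig = field(default_factory=SearchConfig)
    gsva: GsvaConfig = field(default_factory=GsvaConfig)
    gmt: str | None = None
    overlap_mode: str = "exact"
    alpha: float = 0.05
    coverage_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        search = SearchConfig(**raw.pop("search", {}))
        gsva = GsvaConfig(**raw.pop("gsva", {}))
        cfg = cls(search=search, gsva=gsva, **raw)
        missing = [p for p in cfg.input_paths() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        return cfg

    def input_paths(self) -> list[str]:
        paths = [self.network]
        for spec in self.populations.values():
            paths += [spec["expression"], spec["samples"]]
        if self.gmt:
            paths.append(self.gmt)
        return paths

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _crosspop_row(res) -> dict:
    row = {
        "module_id": res.module.module_id,
        "discovery_population": res.discovery_population,
        "k": res.module.k,
        "raw_score": res.module.raw_score,
        "normalized_score": res.module.normalized_score,
        "perm_p": res.module.perm_p,
        "combined_score": res.combined_score,
        "combined_p": res.combined_p,
        "shared": res.shared,
        "members": ";".join(sorted(res.module.members)),
    }
    for pop, es in res.eval_scores.items():
        row[f"z_n_{pop}"] = es.z_n
        row[f"perm_p_{pop}"] = es.perm_p
        row[f"validated_{pop}"] = res.validated.get(pop, False)
    return row


def run_all(config: RunConfig) -> Path:
    """Execute the whole pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "config_hash": config.digest(),
        "seed": config.seed, "stages": {},
    }
    search = SearchConfig(
        config.search.r, config.search.d, config.search.n_perm,
        config.search.top_fraction, seed=config.seed,
    )

    stage = "read_network"
    try:
        graph = read_network(config.network, config.min_confidence)
        manifest["stages"][stage] = {"nodes": graph.number_of_nodes(),
                                     "edges": graph.number_of_edges()}
        weights_by_pop: dict[str, dict] = {}
        expr_by_pop, samples_by_pop = {}, {}
        for pop, spec in sorted(config.populations.items()):
            stage = f"load[{pop}]"
            expr = read_expression(spec["expression"], population=pop)
            table = read_sample_table(spec["samples"])
            stage = f"adjust[{pop}]"
            pc_provenance = "supplied"
            if not table.pc_columns():
                pcs, _ = compute_pcs(expr, config.n_pcs)
                table.frame = table.frame.join(pcs)
                pc_provenance = "expression-derived"
            adj = adjust_covariates(expr, table, config.covariates)
            stage = f"de[{pop}]"
            de = differential_expression(adj, table)
            de.to_csv(out / f"de_{pop}.tsv", sep="\t", index_label="gene_id")
            weights_by_pop[pop] = pvals_to_weights(de)
            expr_by_pop[pop], samples_by_pop[pop] = expr, table
            manifest["stages"][f"de[{pop}]"] = {
                "genes": len(de), "samples": expr.n_samples,
                "covariates": adj.covariates_used, "pcs": pc_provenance,
            }

        stage = "rotation"
        dual = len(config.populations) == 2
        results = run_rotation(
            weights_by_pop, graph, search, config.alpha,
            config.coverage_threshold,
        )
        for disc, res_list in results.items():
            write_modules([r.module for r in res_list],
                          out / f"modules_{disc}.tsv", {"config_hash": config.digest()})
        rows = [_crosspop_row(r) for rl in results.values() for r in rl]
        pd.DataFrame(rows).to_csv(out / "crosspop.tsv", sep="\t", index=False)
        manifest["stages"]["rotation"] = {
            "discovery_rotations": len(results), "dual_cohort_mode": dual,
            "modules": {p: len(r) for p, r in results.items()},
        }

        stage = "overlap"
        validated = {
            pop: [r for r in res if any(r.validated.values())]
            for pop, res in results.items()
        }
        report = overlap_report(validated, mode=config.overlap_mode)
        with open(out / "overlap.tsv", "w") as fh:
            fh.write("populations\tshared_modules\tshared_genes\n")
            for combo in sorted(report.module_counts):
                fh.write(f"{'+'.join(combo)}\t{report.module_counts[combo]}"
                         f"\t{report.gene_counts[combo]}\n")
        all_pops = tuple(sorted(config.populations))
        shared = report.shared_genes.get(all_pops, [])
        pd.Series(shared, name="gene_id").to_csv(
            out / "shared_genes.tsv", sep="\t", index=False)
        manifest["stages"]["overlap"] = {
            "mode": config.overlap_mode,
            "counts": {"+".join(k): v for k, v in report.module_counts.items()},
        }

        if config.gmt:
            stage = "gsva"
            sets = read_gmt(config.gmt)
            for pop in sorted(config.populations):
                scores = gsva_scores(expr_by_pop[pop], sets, config.gsva)
                scores.to_frame().to_csv(out / f"gsva_scores_{pop}.tsv",
                                         sep="\t", index_label="set_name")
                de_sets = gsva_differential(scores, samples_by_pop[pop])
                de_sets.to_csv(out / f"gsva_de_{pop}.tsv", sep="\t",
                               index_label="set_name")
                manifest["stages"][f"gsva[{pop}]"] = {"sets": len(scores.set_names)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
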