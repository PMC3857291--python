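"""End-to-end driver: simulate -> build-ref -> map -> DE -> sets -> enrichment.

Reproduces the shape of a four-library cold-stress tag-profiling
analysis on synthetic data with known truth: one control and three
treatment libraries, three treatment-vs-control comparisons, Venn
partitions of the up/down/novel sets and a GO-slim enrichment of the DE
genes.  Every stage writes its outputs in the documented text dialects,
fails fast with stage-named errors, and the whole run is deterministic
given the configured seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io
from .diffexpr import compare_libraries, volcano_table
from .enrichment import OntologyGraph, hypergeom_enrich, map_to_slim, read_gene2go, read_slim_terms
from .mapping import quantify
from .reference import extract_reference_tags
from .simulate import (
    DEFAULT_CONDITIONS,
    LibrarySpec,
    generate_transcriptome,
    make_annotation,
    make_truth,
    simulate_tag_library,
)
from .timecourse import build_timecourse

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one synthetic end-to-end run."""

    outdir: str = "tagdge_run"
    # synthetic transcriptome
    n_genes: int = 500
    mean_length: int = 789
    catg_density: float = 10.0
    # conditions & libraries
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    control: str = "control"
    depth: int = 100_000
    error_rate: float = 0.01
    # truth
    frac_up: float = 0.06
    frac_down: float = 0.03
    frac_novel: float = 0.01
    fold_change: float = 4.0
    induce_prob: float = 0.6
    baseline_sigma: float = 1.2
    # mapping & DE thresholds
    max_mismatch: int = 1
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    p_max: float = 0.01
    floor_tpm: float = 0.001
    min_count: int = 1
    # enrichment inputs; when unset a synthetic ontology/annotation is used
    obo_path: str | None = None
    slim_path: str | None = None
    gene2go_path: str | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if self.conditions.count(self.control) != 1:
            raise ValueError("exactly one control condition is required")
        if len(self.conditions) != 4:
            raise ValueError("expected a control plus three treatment conditions")
        if not 0 < self.fdr_max <= 1 or not 0 < self.p_max <= 1:
            raise ValueError("fdr_max and p_max must lie in (0, 1]")
        if self.min_abs_log2 < 0 or self.floor_tpm <= 0 or self.min_count < 1:
            raise ValueError("invalid threshold configuration")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")

    @property
    def treatments(self) -> list[str]:
        return [c for c in self.conditions if c != self.control]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _stage(report: dict, name: str):
    """Record a stage entry; exceptions get the stage name prepended."""

    class _Ctx:
        def __enter__(self):
            report["stages"][name] = {}
            return report["stages"][name]

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    master = np.random.default_rng(config.seed)
    lib_seeds = {
        cond: int(s)
        for cond, s in zip(
            config.conditions, master.integers(0, 2**31 - 1, len(config.conditions))
        )
    }
    truth_seed = int(master.integers(0, 2**31 - 1))
    annot_seed = int(master.integers(0, 2**31 - 1))

    with _stage(report, "simulate") as rec:
        transcripts = generate_transcriptome(
            config.n_genes, config.mean_length, config.catg_density, seed=config.seed
        )
        truth = make_truth(
            [t.gene_id for t in transcripts],
            conditions=config.conditions,
            control=config.control,
            frac_up=config.frac_up,
            frac_down=config.frac_down,
            frac_novel=config.frac_novel,
            fold_change=config.fold_change,
            induce_prob=config.induce_prob,
            baseline_sigma=config.baseline_sigma,
            seed=truth_seed,
        )
        io.write_fasta(transcripts, outdir / "transcripts.fa")
        io.write_truth(truth, outdir / "truth.tsv")
        rec["n_genes"] = len(transcripts)
        rec["mean_length"] = float(np.mean([t.length for t in transcripts]))

    with _stage(report, "reference") as rec:
        db = extract_reference_tags(transcripts)
        io.write_refdb(db, outdir / "refdb.tsv", outdir / "refdb_summary.json")
        rec.update(db.summary())

    with _stage(report, "libraries") as rec:
        tables, stats = {}, {}
        for cond in config.conditions:
            spec = LibrarySpec(cond, config.depth, config.error_rate, lib_seeds[cond])
            table, st = simulate_tag_library(transcripts, truth, spec)
            tables[cond], stats[cond] = table, st
            io.write_tag_table(table, outdir / f"tags_{cond}.tsv")
            rec[cond] = {
                "n_raw": st.n_raw,
                "n_clean": st.n_clean,
                "n_dirty": st.n_dirty,
                "n_unobservable_genes": len(st.unobservable_genes),
            }

    with _stage(report, "mapping") as rec:
        counts, expr = {}, {}
        for cond in config.conditions:
            frame, mrep = quantify(tables[cond], db, config.max_mismatch)
            expr[cond] = frame
            counts[cond] = dict(zip(frame["gene_id"], frame["count"].astype(int)))
            io.write_expression(
                frame, outdir / f"expr_{cond}.tsv", cond, tables[cond].library_size
            )
            io.write_json(mrep.to_dict(), outdir / f"mapping_{cond}.json")
            rec[cond] = mrep.to_dict()

    with _stage(report, "diff_expression") as rec:
        de_tables = {}
        n1 = tables[config.control].library_size
        for cond in config.treatments:
            de = compare_libraries(
                counts[config.control],
                counts[cond],
                n1,
                tables[cond].library_size,
                fdr_max=config.fdr_max,
                min_abs_log2=config.min_abs_log2,
                p_max=config.p_max,
                floor_tpm=config.floor_tpm,
            )
            de_tables[cond] = de
            io.write_de_table(de, outdir / f"de_{cond}.tsv")
            io.write_de_table(
                volcano_table(de, config.floor_tpm), outdir / f"volcano_{cond}.tsv"
            )
            sig = de[de["tier"] == "significant"]
            rec[cond] = {
                "n_tested": len(de),
                "n_significant": len(sig),
                "n_difference": int((de["tier"] == "difference").sum()),
                "up": int((sig["direction"] == "up").sum()),
                "down": int((sig["direction"] == "down").sum()),
            }

    with _stage(report, "timecourse") as rec:
        partition = build_timecourse(
            de_tables,
            counts[config.control],
            {c: counts[c] for c in config.treatments},
            config.treatments,
            min_count=config.min_count,
        )
        io.write_json(partition.to_json_dict(), outdir / "venn.json")
        for cond in config.treatments:
            novel = partition.novel_sets[cond]
            with open(outdir / f"novel_{cond}.tsv", "w") as fh:
                fh.write("gene_id\traw_count\n")
                for g in sorted(novel, key=lambda g: (-novel[g], g)):
                    fh.write(f"{g}\t{novel[g]}\n")
        rec.update(partition.summary())

    with _stage(report, "enrichment") as rec:
        if config.obo_path and config.slim_path and config.gene2go_path:
            graph = OntologyGraph.from_obo(config.obo_path)
            slim = read_slim_terms(config.slim_path)
            gene2go = read_gene2go(config.gene2go_path)
        else:
            obo_text, slim, gene2go = make_annotation(
                [t.gene_id for t in transcripts], seed=annot_seed
            )
            obo_path = outdir / "synthetic_go.obo"
            obo_path.write_text(obo_text + "\n")
            graph = OntologyGraph.from_obo(str(obo_path))
        gene2slim = map_to_slim(gene2go, graph, slim)
        study = sorted(
            frozenset().union(
                *(
                    set(de.loc[de["tier"] == "significant", "gene_id"])
                    for de in de_tables.values()
                )
            )
        )
        population = sorted(gene2slim)
        study_in_pop = [g for g in study if g in gene2slim]
        result = hypergeom_enrich(study_in_pop, population, gene2slim, graph)
        for ns in sorted(result["namespace"].unique()):
            sub = result[result["namespace"] == ns]
            io.write_de_table(sub, outdir / f"enrichment_{ns}.tsv")
        rec["n_study"] = len(study_in_pop)
        rec["n_population"] = len(population)
        rec["n_terms"] = len(result)
        rec["min_p"] = float(result["p_value"].min()) if len(result) else 1.0

    with _stage(report, "truth_recovery") as rec:
        for cond in config.treatments:
            de = de_tables[cond]
            sig = de[de["tier"] == "significant"]
            called_up = set(sig.loc[sig["direction"] == "up", "gene_id"])
            called_down = set(sig.loc[sig["direction"] == "down", "gene_id"])
            true_up = truth.genes_with_direction(cond, "up")
            true_down = truth.genes_with_direction(cond, "down")
            called = called_up | called_down
            true_de = true_up | true_down
            tp = len(called_up & true_up) + len(called_down & true_down)
            rec[cond] = {
                "n_true_de": len(true_de),
                "n_called": len(called),
                "sensitivity": tp / len(true_de) if true_de else float("nan"),
                "precision": tp / len(called) if called else float("nan"),
            }

    io.write_json(report, outdir / "report.json")
    io.write_json(config.to_dict(), outdir / "config_resolved.json")
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["tagdge run report", "=" * 40]
    for name, rec in report["stages"].items():
        lines.append(f"[{name}]")
        for key, value in rec.items():
            lines.append(f"  {key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")
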