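"""End-to-end orchestration: simulate -> annotate -> quantify -> test ->
classify -> profile, with a machine-readable run summary.

Every stage reads its inputs from files and writes its outputs to files,
so stage outputs are pure functions of stage inputs and a fixed seed
makes the whole run byte-reproducible.  The summary JSON echoes the
configuration and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    DEFAULT_EVALUE_THRESHOLD,
    AnnotationAssignment,
    assign_best_hit,
    cluster_unigenes,
    filter_hits,
)
from .classification import (
    assign_cluster,
    build_tf_catalog,
    load_tf_lexicon,
    partition_summary,
)
from .diffexp import DEResult, NBModelParams, de_results_frame, run_de
from .functional_profiling import ec_pathway_profile, load_default_ec_pathway_map, term_frequencies
from .io_formats import (
    read_annotations,
    read_assembly,
    read_blast_tab,
    read_catalog,
    read_ec_pathway_map,
    read_ontology,
)
from .quantification import ExpressionRecord, build_expression_table
from .synthetic_data import SimConfig, simulate_dataset, truth_eval, write_dataset

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One configuration for a full pipeline run."""

    outdir: str = "run"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    phi: float = 0.1
    alpha: float = 0.01
    pseudocount: float = 0.5
    two_sided_rule: str = "minlike"
    use_slim: bool = True
    nearest_only_slim: bool = False
    tf_lexicon: str | None = None
    ec_pathway_map: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        for key, value in sim.items():  # YAML lists -> tuple-typed fields
            if isinstance(value, list):
                sim[key] = tuple(value)
        return SimConfig(seed=self.seed, **sim)

    def nb_params(self) -> NBModelParams:
        return NBModelParams(self.phi, self.alpha, self.pseudocount, self.two_sided_rule)


# ---------------------------------------------------------------------------
# intermediate table round-trips
# ---------------------------------------------------------------------------


def write_assignments(assignments, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("isotig_id\tprotein_id\tevalue\tbitscore\n")
        for a in assignments:
            fh.write(f"{a.isotig_id}\t{a.protein_id}\t{a.evalue:.6e}\t{a.bitscore:.1f}\n")


def read_assignments(path) -> list:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        AnnotationAssignment(r.isotig_id, r.protein_id, float(r.evalue), float(r.bitscore))
        for r in frame.itertuples(index=False)
    ]


def write_expression_tsv(records: list[ExpressionRecord], path) -> None:
    if records:
        samples = records[0].sample_ids
    else:
        samples = ()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = ["unigene", "L_nt"]
        cols += [f"C_{s}" for s in samples]
        cols += [f"N_{s}" for s in samples]
        cols += [f"RPKMx1000_{s}" for s in samples]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.unigene_id, str(r.protein_nt_length)]
            row += [str(r.raw_count[s]) for s in samples]
            row += [str(r.library_size[s]) for s in samples]
            row += [f"{r.rpkm[s] * 1000:.2f}" for s in samples]
            fh.write("\t".join(row) + "\n")


def read_expression_tsv(path) -> list[ExpressionRecord]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    samples = tuple(c[2:] for c in frame.columns if c.startswith("C_"))
    records = []
    for r in frame.itertuples(index=False):
        d = r._asdict()
        counts = {s: int(d[f"C_{s}"]) for s in samples}
        library = {s: int(d[f"N_{s}"]) for s in samples}
        length = int(d["L_nt"])
        records.append(
            ExpressionRecord(
                unigene_id=d["unigene"],
                sample_ids=samples,
                raw_count=counts,
                rpkm={s: 1e9 * counts[s] / (library[s] * length) for s in samples},
                library_size=library,
                protein_nt_length=length,
            )
        )
    return records


def read_de_tsv(path) -> list[DEResult]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    y_cols = [c for c in frame.columns if c.startswith("y_")]
    return [
        DEResult(
            d["unigene"],
            (int(d[y_cols[0]]), int(d[y_cols[1]])),
            float(d["logFC"]),
            float(d["pvalue"]),
            bool(d["significant"]),
            float(d["padj_BH"]),
        )
        for d in (r._asdict() for r in frame.itertuples(index=False))
    ]


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    datadir = outdir / "data"
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        sim_cfg = config.sim_config()
        sim = simulate_dataset(sim_cfg)
        paths = write_dataset(sim, datadir)
        sample_ids = sim_cfg.sample_ids

        stage = "annotate"
        assembly = read_assembly(paths["contigs"], paths["isotigs"], sample_ids)
        hits = read_blast_tab(paths["hits"])
        catalog = read_catalog(paths["catalog"])
        kept = filter_hits(hits, config.evalue_threshold)
        assignments = assign_best_hit(kept)
        clusters = cluster_unigenes(assignments, catalog)
        write_assignments(assignments, outdir / "unigenes.tsv")

        stage = "quantify"
        expression = build_expression_table(clusters, assembly)
        write_expression_tsv(expression, outdir / "expression.tsv")

        stage = "detest"
        de_results = run_de(expression, config.nb_params())
        de_results_frame(de_results, sample_ids).to_csv(outdir / "de.tsv", sep="\t", index=False)

        stage = "classify"
        expr_by_id = {r.unigene_id: r for r in expression}
        labels = {r.unigene_id: assign_cluster(r, expr_by_id[r.unigene_id]) for r in de_results}
        pd.DataFrame(sorted(labels.items()), columns=["unigene", "label"]).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        summary_part = partition_summary(labels)
        venn = {
            "fruit_only": summary_part.venn_a_only,
            "az_only": summary_part.venn_b_only,
            "common": summary_part.venn_common,
            "fruit_total": summary_part.side_a_total,
            "az_total": summary_part.side_b_total,
        }
        (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        lexicon = load_tf_lexicon(config.tf_lexicon)
        tf_entries = build_tf_catalog(labels, catalog, lexicon)
        pd.DataFrame(
            [(e.unigene_id, e.family, e.cluster) for e in tf_entries],
            columns=["unigene", "family", "cluster"],
        ).to_csv(outdir / "tf_catalog.tsv", sep="\t", index=False)

        stage = "profile"
        ontology = read_ontology(paths["ontology"], paths["slim"])
        annotations = read_annotations(paths["annotations"])
        side_a = {u for u, lab in labels.items() if lab in ("A1", "A2")}
        side_b = {u for u, lab in labels.items() if lab in ("B1", "B2")}
        freq = term_frequencies(
            {"fruit_over": side_a, "az_over": side_b},
            annotations,
            ontology,
            use_slim=config.use_slim,
            nearest_only=config.nearest_only_slim,
        )
        freq.to_csv(outdir / "go_freq.tsv", sep="\t", index=False)
        ec_map = (
            read_ec_pathway_map(config.ec_pathway_map)
            if config.ec_pathway_map
            else load_default_ec_pathway_map()
        )
        profile = ec_pathway_profile(side_a | side_b, catalog, ec_map)
        profile.to_frame().to_csv(outdir / "pathway_profile.tsv", sep="\t", index=False)

        stage = "eval-truth"
        evaluation = truth_eval(de_results, sim.manifest)
    except Exception as exc:  # annotate failures with the stage that died
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "evalue_threshold": config.evalue_threshold,
            "phi": config.phi,
            "alpha": config.alpha,
            "pseudocount": config.pseudocount,
            "two_sided_rule": config.two_sided_rule,
            "use_slim": config.use_slim,
            "sim": dict(config.sim),
        },
        "counts": {
            "isotigs_annotated": len(assignments),
            "unigenes": len(clusters),
            "degs": sum(1 for r in de_results if r.significant),
            "clusters": summary_part.counts,
            "tf_degs": len(tf_entries),
            "pathways": len(profile.ec_sets),
        },
        "truth_eval": {
            "tp": evaluation.tp,
            "fp": evaluation.fp,
            "fn": evaluation.fn,
            "tn": evaluation.tn,
            "tpr": evaluation.tpr,
            "fpr": evaluation.fpr,
            "logfc_bias": evaluation.logfc_bias,
            "logfc_rmse": evaluation.logfc_rmse,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
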