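"""Synthetic two-sample, no-replicate 454-style datasets with known truth.

The generator emulates the study design the pipeline targets: two cDNA
libraries (ripe-fruit pericarp and abscission zone), each sequenced
once, assembled into contigs carrying the raw read counts and isotigs
(isoform paths over contigs, 1-3 per gene, possibly sharing contigs),
annotated against a reference-protein catalog by E-value-filtered hits.

Count model, per gene g and sample i: a gene-level draw
Y_gi ~ NB(mean = M_i * p_gi, dispersion = phi), variance mu + phi*mu^2
(phi = 0 gives Poisson), then a multinomial split of Y_gi across the
gene's contigs proportional to contig length.  Because every contig of
a gene is covered by its isotigs, the deduplicated unigene count
recovers Y_gi exactly, giving every downstream stage a clean truth
value.

Differential expression is built in balanced up/down pairs that share a
baseline abundance, so the per-sample abundance vectors sum to one
without renormalization and null genes have a true logFC of exactly 0.
Exclusive genes (zero true abundance in one tissue) are likewise
paired, one per tissue.  DE status is assigned to the leading genes
deterministically; randomness only enters through per-gene draw
substreams (one child seed per gene), so enlarging ``n_genes`` never
reshuffles the draws of earlier genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (
    AssemblyDataset,
    BlastHitRecord,
    ContigRecord,
    IsotigRecord,
    OntologyBundle,
    ProteinCatalogRecord,
    write_annotations,
    write_assembly,
    write_blast_tab,
    write_catalog,
    write_ec_pathway_map,
    write_ontology_edges,
    write_slim,
)

__all__ = ["SimConfig", "GeneTruth", "TruthManifest", "SimulatedDataset",
           "simulate_dataset", "write_dataset", "truth_eval", "TruthEvalSummary"]

_DESCRIPTIONS = [
    "Beta-glucosidase",
    "Thaumatin-like protein",
    "Polygalacturonase",
    "Expansin",
    "Chalcone synthase",
    "ACC oxidase",
    "Ethylene receptor",
    "Beta-1,3-glucanase",
    "Pectinesterase",
    "Anthocyanidin synthase",
    "Serine-threonine protein kinase",
    "Arginine decarboxylase",
    "Purple acid phosphatase",
    "Glutamine synthetase",
    "Nitrate transporter",
    "Uncharacterized protein",
    "Tubulin beta chain",
    "Sucrose synthase",
    "Alpha-amylase",
    "Cysteine synthase",
]

_TF_DESCRIPTIONS = [
    "MADS-box protein AGL9",
    "WRKY transcription factor 30",
    "Heat shock factor protein 4",
    "GRAS family protein",
    "GAGA-binding transcriptional activator BBR",
    "EIN3-like protein",
    "E2F transcription factor",
    "CCAAT-binding factor subunit",
    "CAMTA1 calmodulin-binding transcription activator",
    "C2H2 type zinc finger protein",
    "Aux/IAA protein IAA1",
    "AP2 domain-containing protein ERF3",
    "NAC domain protein",
    "MYB transcription factor MYBPA1",
    "bZIP transcription factor HY5",
    "bHLH transcription factor MYC2",
    "Homeobox protein knotted-1, KNOX",
    "Zinc finger protein ZFP2",
    "SBP-box protein SPL3",
    "Auxin response factor ARF5",
]


@dataclass(frozen=True)
class SimConfig:
    """Conditions of the emulated two-tissue, one-library-each experiment.

    Library-size defaults are the per-tissue read totals of the olive
    study design this generator emulates; the DE fraction and the share
    of exclusive genes default to the proportions observed there.
    """

    n_genes: int = 300
    sample_ids: tuple[str, str] = ("fruit", "az")
    library_sizes: tuple[int, int] = (199075, 198382)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    contigs_per_isotig: tuple[int, int] = (1, 4)
    shared_contig_prob: float = 0.5
    contig_length_range: tuple[int, int] = (200, 800)
    aa_length_range: tuple[int, int] = (100, 600)
    abundance_sigma: float = 1.0
    phi: float = 0.1
    de_fraction: float = 0.57
    logfc_effect: float = 2.0
    exclusive_fraction: float = 0.7
    decoy_hit_rate: float = 0.3
    true_evalue_range: tuple[float, float] = (1e-180, 1e-30)
    decoy_evalue_range: tuple[float, float] = (1e-18, 1e-3)
    tf_fraction: float = 0.05
    ec_fraction: float = 0.2
    go_terms_per_gene: tuple[int, int] = (1, 5)
    ontology_terms_per_namespace: int = 30
    slim_terms_per_namespace: int = 5
    cross_gene_sharing: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in (self.shared_contig_prob, self.de_fraction, self.exclusive_fraction,
                  self.decoy_hit_rate, self.tf_fraction, self.ec_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(m < 1 for m in self.library_sizes):
            raise ValueError("library sizes must be >= 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        for lo, hi in (self.isoforms_per_gene, self.contigs_per_isotig,
                       self.contig_length_range, self.aa_length_range,
                       self.go_terms_per_gene):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")


@dataclass(frozen=True)
class GeneTruth:
    protein_id: str
    p: dict  # sample -> true relative abundance
    true_logfc: float
    is_de: bool
    is_exclusive: bool
    isotigs: tuple[str, ...]
    contigs: tuple[str, ...]


@dataclass
class TruthManifest:
    sample_ids: tuple[str, str]
    genes: list  # list[GeneTruth]

    def by_id(self) -> dict:
        return {g.protein_id: g for g in self.genes}

    def validate(self) -> None:
        for s in self.sample_ids:
            total = sum(g.p[s] for g in self.genes)
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError(f"abundances for {s} sum to {total}, not 1")
        for g in self.genes:
            if not g.is_de and g.true_logfc != 0.0:
                raise ValueError(f"null gene {g.protein_id} has true logFC {g.true_logfc}")


@dataclass
class SimulatedDataset:
    config: SimConfig
    assembly: AssemblyDataset
    hits: list
    catalog: dict
    ontology: OntologyBundle
    manifest: TruthManifest

    @property
    def annotations(self) -> dict:
        """protein -> GO terms, as inherited by the unigene it annotates."""
        return {pid: set(rec.go_terms) for pid, rec in self.catalog.items()}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _de_plan(config: SimConfig) -> list[tuple[bool, bool, int]]:
    """(is_de, is_exclusive, direction) per gene; directions alternate +1/-1.

    DE genes lead the gene list and come in balanced up/down pairs; the
    exclusive pairs lead the DE block.  Counts are rounded down to even
    so every pair is complete.
    """
    n_de = int(round(config.n_genes * config.de_fraction)) // 2 * 2
    n_excl = int(round(n_de * config.exclusive_fraction)) // 2 * 2
    plan = []
    for g in range(config.n_genes):
        if g < n_de:
            plan.append((True, g < n_excl, +1 if g % 2 == 0 else -1))
        else:
            plan.append((False, False, 0))
    return plan


def _make_ontology(rng: np.random.Generator, config: SimConfig) -> OntologyBundle:
    namespace_of, name_of, edges = {}, {}, []
    slim: set[str] = set()
    namespaces = ("biological_process", "molecular_function", "cellular_component")
    counter = 1
    for ns in namespaces:
        terms = []
        for i in range(config.ontology_terms_per_namespace):
            term = f"GO:{counter:07d}"
            counter += 1
            namespace_of[term] = ns
            name_of[term] = f"{ns} term {i}"
            if terms:
                n_parents = 1 if i < 3 or rng.random() < 0.7 else 2
                parents = rng.choice(len(terms), size=min(n_parents, len(terms)), replace=False)
                for pi in parents:
                    rel = "is_a" if rng.random() < 0.8 else "part_of"
                    edges.append((term, terms[int(pi)], rel))
            terms.append(term)
        k = min(config.slim_terms_per_namespace, len(terms))
        slim.update(terms[int(i)] for i in rng.choice(len(terms), size=k, replace=False))
    bundle = OntologyBundle(namespace_of, name_of, edges, frozenset(slim))
    bundle.validate()
    return bundle


def _log_uniform(rng, lo, hi):
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete dataset plus its truth manifest.

    Substream order: child seed 0 of ``SeedSequence(config.seed)`` drives
    the ontology and shared vocab choices; child ``g + 1`` drives every
    draw of gene ``g`` (structure, abundance, counts, hit E-values).
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_genes + 1)
    rng_global = np.random.default_rng(children[0])

    ontology = _make_ontology(rng_global, config)
    all_terms = sorted(ontology.terms)
    from .functional_profiling import load_default_ec_pathway_map

    ec_vocab = sorted({ec for ec, _ in load_default_ec_pathway_map()})

    plan = _de_plan(config)
    lfc = config.logfc_effect
    up, down = 2.0 ** (lfc / 2.0), 2.0 ** (-lfc / 2.0)

    contigs: dict[str, ContigRecord] = {}
    isotigs: dict[str, IsotigRecord] = {}
    catalog: dict[str, ProteinCatalogRecord] = {}
    hits: list[BlastHitRecord] = []
    gene_rows = []  # (protein_id, weights per sample, gene contigs, gene isotigs, rng)

    s1, s2 = config.sample_ids
    baseline_carry = None  # baseline shared within a DE pair
    for g in range(config.n_genes):
        rng = np.random.default_rng(children[g + 1])
        pid = f"P{g:05d}"
        is_de, is_excl, direction = plan[g]

        # --- abundance weights (unnormalized; pairs balance by construction)
        if is_de and direction == -1 and baseline_carry is not None:
            baseline = baseline_carry
            rng.lognormal(0.0, config.abundance_sigma)  # keep substream aligned
        else:
            baseline = float(rng.lognormal(0.0, config.abundance_sigma))
        if is_de and direction == +1:
            baseline_carry = baseline
        if not is_de:
            w1 = w2 = baseline
            true_logfc = 0.0
        elif is_excl:
            w1, w2 = (baseline, 0.0) if direction == +1 else (0.0, baseline)
            true_logfc = math.inf if direction == +1 else -math.inf
        else:
            w1, w2 = (baseline * up, baseline * down) if direction == +1 else (baseline * down, baseline * up)
            true_logfc = lfc * direction

        # --- structure: contigs and isotigs
        n_iso = int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1))
        gene_contigs: list[str] = []
        gene_isotigs: list[str] = []
        for j in range(n_iso):
            n_c = int(rng.integers(config.contigs_per_isotig[0], config.contigs_per_isotig[1] + 1))
            members: list[str] = []
            for _slot in range(n_c):
                reusable = [c for c in gene_contigs if c not in members]
                if j > 0 and reusable and rng.random() < config.shared_contig_prob:
                    members.append(reusable[int(rng.integers(len(reusable)))])
                else:
                    cid = f"c{g:05d}_{len(gene_contigs):02d}"
                    length = int(rng.integers(config.contig_length_range[0],
                                              config.contig_length_range[1] + 1))
                    contigs[cid] = ContigRecord(cid, length, {s1: 0, s2: 0})
                    gene_contigs.append(cid)
                    members.append(cid)
            iid = f"iso{g:05d}_{j}"
            isotigs[iid] = IsotigRecord(iid, tuple(members))
            gene_isotigs.append(iid)
        # every contig is created inside some isotig's member list, so the
        # union of the gene's isotigs covers all its contigs: the
        # deduplicated unigene count recovers the gene-level draw exactly

        # --- catalog entry
        aa_len = int(rng.integers(config.aa_length_range[0], config.aa_length_range[1] + 1))
        if rng.random() < config.tf_fraction:
            desc = _TF_DESCRIPTIONS[int(rng.integers(len(_TF_DESCRIPTIONS)))]
        else:
            desc = _DESCRIPTIONS[int(rng.integers(len(_DESCRIPTIONS)))]
        n_go = int(rng.integers(config.go_terms_per_gene[0], config.go_terms_per_gene[1] + 1))
        go_terms = frozenset(all_terms[int(i)] for i in rng.choice(len(all_terms), size=n_go, replace=False))
        ec_codes = frozenset()
        if rng.random() < config.ec_fraction:
            n_ec = int(rng.integers(1, 3))
            ec_codes = frozenset(ec_vocab[int(i)] for i in rng.choice(len(ec_vocab), size=n_ec, replace=False))
        catalog[pid] = ProteinCatalogRecord(pid, aa_len, desc, go_terms, ec_codes)

        # --- annotation hits: one true hit per isotig, decoys above threshold
        for iid in gene_isotigs:
            ev = _log_uniform(rng, *config.true_evalue_range)
            bitscore = round(80.0 - 1.5 * math.log10(ev) + rng.uniform(0, 20), 1)
            hits.append(BlastHitRecord(iid, pid, round(rng.uniform(60, 99), 2), aa_len, 0, 0,
                                       1, 3 * aa_len, 1, aa_len, ev, bitscore))
            if rng.random() < config.decoy_hit_rate:
                # single-uniform index draw: stream consumption does not
                # depend on n_genes, keeping per-gene substreams stable
                other = f"P{int(rng.random() * config.n_genes):05d}"
                ev_d = _log_uniform(rng, *config.decoy_evalue_range)
                hits.append(BlastHitRecord(iid, other, round(rng.uniform(30, 60), 2), aa_len // 2, 0, 0,
                                           1, aa_len, 1, aa_len // 2, ev_d,
                                           round(40.0 + rng.uniform(0, 20), 1)))

        gene_rows.append((pid, (w1, w2), tuple(gene_contigs), tuple(gene_isotigs), rng, true_logfc,
                          is_de, is_excl))

    # --- normalize abundances (totals are equal across samples by pairing)
    t1 = sum(row[1][0] for row in gene_rows)
    t2 = sum(row[1][1] for row in gene_rows)
    genes: list[GeneTruth] = []
    for pid, (w1, w2), gcontigs, gisotigs, rng, true_logfc, is_de, is_excl in gene_rows:
        p1, p2 = w1 / t1, w2 / t2
        # --- gene-level NB draw, then multinomial split over contigs by length
        counts = {}
        for sample, m, p in ((s1, config.library_sizes[0], p1), (s2, config.library_sizes[1], p2)):
            mu = m * p
            if mu == 0:
                y = 0
            elif config.phi == 0:
                y = int(rng.poisson(mu))
            else:
                r = 1.0 / config.phi
                y = int(rng.negative_binomial(r, r / (r + mu)))
            counts[sample] = y
        lengths = np.array([contigs[c].length_nt for c in gcontigs], dtype=float)
        weights = lengths / lengths.sum()
        for sample in (s1, s2):
            split = rng.multinomial(counts[sample], weights)
            for cid, extra in zip(gcontigs, split):
                old = contigs[cid]
                reads = dict(old.reads_per_sample)
                reads[sample] += int(extra)
                contigs[cid] = ContigRecord(cid, old.length_nt, reads)
        genes.append(GeneTruth(pid, {s1: p1, s2: p2}, true_logfc, is_de, is_excl,
                               gisotigs, gcontigs))

    assembly = AssemblyDataset(config.sample_ids, contigs, isotigs)
    assembly.validate()
    manifest = TruthManifest(config.sample_ids, genes)
    manifest.validate()
    return SimulatedDataset(config, assembly, hits, catalog, ontology, manifest)


def write_dataset(sim: SimulatedDataset, outdir) -> dict:
    """Write every pipeline input plus truth.tsv; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.tsv",
        "isotigs": outdir / "isotigs.tsv",
        "hits": outdir / "hits.tsv",
        "catalog": outdir / "catalog.tsv",
        "ontology": outdir / "ontology_edges.tsv",
        "slim": outdir / "slim.txt",
        "annotations": outdir / "annotations.tsv",
        "ec_pathway": outdir / "ec2pathway.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_assembly(sim.assembly, paths["contigs"], paths["isotigs"])
    write_blast_tab(sim.hits, paths["hits"])
    write_catalog(sim.catalog, paths["catalog"])
    write_ontology_edges(sim.ontology, paths["ontology"])
    write_slim(sim.ontology.slim_set, paths["slim"])
    write_annotations(sim.annotations, paths["annotations"])
    from .functional_profiling import load_default_ec_pathway_map

    write_ec_pathway_map(load_default_ec_pathway_map(), paths["ec_pathway"])
    s1, s2 = sim.manifest.sample_ids
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"protein_id\tp_{s1}\tp_{s2}\ttrue_logfc\tis_de\tis_exclusive\tisotigs\tcontigs\n")
        for g in sim.manifest.genes:
            fh.write(
                f"{g.protein_id}\t{g.p[s1]:.10e}\t{g.p[s2]:.10e}\t{g.true_logfc}\t"
                f"{int(g.is_de)}\t{int(g.is_exclusive)}\t{','.join(g.isotigs)}\t{','.join(g.contigs)}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthEvalSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    logfc_bias: float
    logfc_rmse: float

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")


def truth_eval(de_results, manifest: TruthManifest) -> TruthEvalSummary:
    """Confusion counts and logFC accuracy of a DE caller against truth.

    LogFC bias and RMSE are computed over the DE genes with a finite
    true logFC (exclusive genes have an infinite one and are skipped).
    """
    truth = manifest.by_id()
    result_ids = {r.unigene_id for r in de_results}
    if result_ids != set(truth):
        missing = sorted(set(truth) - result_ids)[:3]
        extra = sorted(result_ids - set(truth))[:3]
        raise ValueError(f"gene id mismatch: missing={missing} extra={extra}")
    tp = fp = fn = tn = 0
    errors = []
    for r in de_results:
        g = truth[r.unigene_id]
        if g.is_de and r.significant:
            tp += 1
        elif g.is_de:
            fn += 1
        elif r.significant:
            fp += 1
        else:
            tn += 1
        if g.is_de and math.isfinite(g.true_logfc):
            errors.append(r.logfc - g.true_logfc)
    bias = float(np.mean(errors)) if errors else float("nan")
    rmse = float(np.sqrt(np.mean(np.square(errors)))) if errors else float("nan")
    return TruthEvalSummary(tp, fp, fn, tn, bias, rmse)
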