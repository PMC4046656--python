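"""Readers and writers for every external file the pipeline touches.

All tabular formats are UTF-8 TSV with a header row, ``.`` decimal
separator and ``#`` comment lines; alignment hits use the standard
header-less 12-column BLAST tabular layout (``-outfmt 6``).  Readers
validate strictly and raise :class:`FormatError` naming the file and
line of the first offending field, so a corrupted input never flows
silently into the analysis.  Writers are deterministic: reading a file
and writing it back is byte-stable once the file is in canonical form.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ContigRecord",
    "IsotigRecord",
    "AssemblyDataset",
    "BlastHitRecord",
    "ProteinCatalogRecord",
    "OntologyBundle",
    "EC_PATTERN",
    "read_assembly",
    "write_assembly",
    "read_blast_tab",
    "write_blast_tab",
    "read_catalog",
    "write_catalog",
    "read_ontology",
    "write_ontology_edges",
    "write_obo",
    "read_annotations",
    "write_annotations",
    "read_ec_pathway_map",
    "write_ec_pathway_map",
    "read_fasta",
    "write_fasta",
]

#: Four-level Enzyme Commission code; unresolved trailing levels may be ``-``.
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class FormatError(ValueError):
    """A located parse/validation error in an external file."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig: the unit raw reads are attached to."""

    contig_id: str
    length_nt: int
    reads_per_sample: Mapping[str, int]

    def __post_init__(self):
        if self.length_nt < 1:
            raise ValueError(f"contig {self.contig_id}: length_nt must be >= 1")
        for sample, n in self.reads_per_sample.items():
            if n < 0:
                raise ValueError(f"contig {self.contig_id}: negative count for {sample}")


@dataclass(frozen=True)
class IsotigRecord:
    """An isoform path over contigs (one putative transcript)."""

    isotig_id: str
    member_contigs: tuple[str, ...]

    def __post_init__(self):
        if not self.member_contigs:
            raise ValueError(f"isotig {self.isotig_id}: no member contigs")
        if len(set(self.member_contigs)) != len(self.member_contigs):
            raise ValueError(f"isotig {self.isotig_id}: duplicate member contig")


@dataclass
class AssemblyDataset:
    """Contigs with per-sample read counts plus isotig membership."""

    sample_ids: tuple[str, ...]
    contigs: dict[str, ContigRecord]
    isotigs: dict[str, IsotigRecord]

    def validate(self) -> None:
        for c in self.contigs.values():
            missing = [s for s in self.sample_ids if s not in c.reads_per_sample]
            if missing:
                raise ValueError(f"contig {c.contig_id}: missing counts for {missing}")
        for iso in self.isotigs.values():
            for cid in iso.member_contigs:
                if cid not in self.contigs:
                    raise ValueError(
                        f"isotig {iso.isotig_id} references unknown contig {cid!r}"
                    )

    def library_size(self, sample_id: str) -> int:
        """Total reads in a sample across *all* contigs."""
        if sample_id not in self.sample_ids:
            raise KeyError(f"unknown sample {sample_id!r}")
        return sum(c.reads_per_sample[sample_id] for c in self.contigs.values())


@dataclass(frozen=True)
class BlastHitRecord:
    """One line of 12-column BLAST tabular output."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not self.query_id or not self.subject_id:
            raise ValueError("empty query/subject id")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")


@dataclass(frozen=True)
class ProteinCatalogRecord:
    """A reference protein (UniRef90-representative style)."""

    protein_id: str
    aa_length: int
    description: str = ""
    go_terms: frozenset[str] = frozenset()
    ec_codes: frozenset[str] = frozenset()
    tf_family: str | None = None

    def __post_init__(self):
        if self.aa_length < 1:
            raise ValueError(f"protein {self.protein_id}: aa_length must be >= 1")
        for ec in self.ec_codes:
            if not EC_PATTERN.match(ec):
                raise ValueError(f"protein {self.protein_id}: malformed EC {ec!r}")


ProteinCatalog = dict  # protein_id -> ProteinCatalogRecord


@dataclass
class OntologyBundle:
    """A GO-style DAG, a slim subset, and term metadata.

    Only ``is_a`` and ``part_of`` edges are traversed; the graph runs
    child -> parent, so ancestors of a term are its descendants in
    ``graph``.
    """

    namespace_of: dict[str, str]
    name_of: dict[str, str]
    edges: list[tuple[str, str, str]]  # (child, parent, relation)
    slim_set: frozenset[str] = frozenset()
    _graph: nx.DiGraph | None = field(default=None, repr=False, compare=False)

    TRAVERSED_RELATIONS = ("is_a", "part_of")

    @property
    def terms(self) -> set[str]:
        return set(self.namespace_of)

    @property
    def graph(self) -> nx.DiGraph:
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.namespace_of)
            for child, parent, rel in self.edges:
                if rel in self.TRAVERSED_RELATIONS:
                    g.add_edge(child, parent)
            self._graph = g
        return self._graph

    def validate(self) -> None:
        for child, parent, _rel in self.edges:
            if child not in self.namespace_of or parent not in self.namespace_of:
                raise ValueError(f"edge ({child}, {parent}) has endpoint outside terms")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        stray = self.slim_set - self.terms
        if stray:
            raise ValueError(f"slim terms absent from ontology: {sorted(stray)}")


# ---------------------------------------------------------------------------
# low-level TSV plumbing
# ---------------------------------------------------------------------------


def _tsv_rows(path):
    """Yield (lineno, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_int(value, path, lineno, what, minimum=None):
    try:
        n = int(value)
    except ValueError:
        raise FormatError(path, lineno, f"{what}: {value!r} is not an integer") from None
    if minimum is not None and n < minimum:
        raise FormatError(path, lineno, f"{what}: {n} < {minimum}")
    return n


def _parse_float(value, path, lineno, what):
    try:
        return float(value)
    except ValueError:
        raise FormatError(path, lineno, f"{what}: {value!r} is not a number") from None


def _require_columns(header, required, path, lineno):
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(path, lineno, f"missing column(s) {missing}; header={header}")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def read_assembly(contig_path, isotig_path, sample_ids: Sequence[str]) -> AssemblyDataset:
    """Read contig counts and isotig membership into an :class:`AssemblyDataset`.

    ``contigs.tsv`` columns: ``contig_id``, ``length_nt``, ``reads_<sample>`` per
    declared sample.  ``isotigs.tsv`` columns: ``isotig_id``, ``contigs``
    (comma-joined contig ids).
    """
    sample_ids = tuple(sample_ids)
    rows = _tsv_rows(contig_path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(contig_path, 0, "empty file") from None
    read_cols = [f"reads_{s}" for s in sample_ids]
    _require_columns(header, ["contig_id", "length_nt", *read_cols], contig_path, header_lineno)
    idx = {col: header.index(col) for col in header}

    contigs: dict[str, ContigRecord] = {}
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise FormatError(contig_path, lineno, f"expected {len(header)} columns, got {len(fields)}")
        cid = fields[idx["contig_id"]]
        if cid in contigs:
            raise FormatError(contig_path, lineno, f"duplicate contig_id {cid!r}")
        length = _parse_int(fields[idx["length_nt"]], contig_path, lineno, "length_nt", minimum=1)
        reads = {
            s: _parse_int(fields[idx[f"reads_{s}"]], contig_path, lineno, f"reads_{s}", minimum=0)
            for s in sample_ids
        }
        contigs[cid] = ContigRecord(cid, length, reads)

    rows = _tsv_rows(isotig_path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(isotig_path, 0, "empty file") from None
    _require_columns(header, ["isotig_id", "contigs"], isotig_path, header_lineno)
    idx = {col: header.index(col) for col in header}

    isotigs: dict[str, IsotigRecord] = {}
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise FormatError(isotig_path, lineno, f"expected {len(header)} columns, got {len(fields)}")
        iid = fields[idx["isotig_id"]]
        if iid in isotigs:
            raise FormatError(isotig_path, lineno, f"duplicate isotig_id {iid!r}")
        members = tuple(m for m in fields[idx["contigs"]].split(",") if m)
        if not members:
            raise FormatError(isotig_path, lineno, f"isotig {iid!r} lists no contigs")
        if len(set(members)) != len(members):
            raise FormatError(isotig_path, lineno, f"isotig {iid!r} lists a contig twice")
        for m in members:
            if m not in contigs:
                raise FormatError(isotig_path, lineno, f"isotig {iid!r} references unknown contig {m!r}")
        isotigs[iid] = IsotigRecord(iid, members)

    dataset = AssemblyDataset(sample_ids, contigs, isotigs)
    dataset.validate()
    return dataset


def write_assembly(dataset: AssemblyDataset, contig_path, isotig_path) -> None:
    with open(contig_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("contig_id\tlength_nt\t" + "\t".join(f"reads_{s}" for s in dataset.sample_ids) + "\n")
        for cid in sorted(dataset.contigs):
            c = dataset.contigs[cid]
            counts = "\t".join(str(c.reads_per_sample[s]) for s in dataset.sample_ids)
            fh.write(f"{cid}\t{c.length_nt}\t{counts}\n")
    with open(isotig_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("isotig_id\tcontigs\n")
        for iid in sorted(dataset.isotigs):
            fh.write(f"{iid}\t{','.join(dataset.isotigs[iid].member_contigs)}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------


def read_blast_tab(path) -> list[BlastHitRecord]:
    """Read header-less 12-column BLAST tabular (``-outfmt 6``) hits."""
    hits = []
    for lineno, fields in _tsv_rows(path):
        if len(fields) != 12:
            raise FormatError(path, lineno, f"expected 12 columns, got {len(fields)}")
        q, s = fields[0], fields[1]
        if not q or not s:
            raise FormatError(path, lineno, "empty query or subject id")
        evalue = _parse_float(fields[10], path, lineno, "evalue")
        if evalue < 0:
            raise FormatError(path, lineno, f"negative evalue {evalue}")
        hits.append(
            BlastHitRecord(
                query_id=q,
                subject_id=s,
                percent_identity=_parse_float(fields[2], path, lineno, "percent_identity"),
                align_length=_parse_int(fields[3], path, lineno, "align_length"),
                mismatches=_parse_int(fields[4], path, lineno, "mismatches"),
                gap_opens=_parse_int(fields[5], path, lineno, "gap_opens"),
                q_start=_parse_int(fields[6], path, lineno, "q_start"),
                q_end=_parse_int(fields[7], path, lineno, "q_end"),
                s_start=_parse_int(fields[8], path, lineno, "s_start"),
                s_end=_parse_int(fields[9], path, lineno, "s_end"),
                evalue=evalue,
                bitscore=_parse_float(fields[11], path, lineno, "bitscore"),
            )
        )
    return hits


def write_blast_tab(hits: Iterable[BlastHitRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        repr(h.percent_identity),  # shortest lossless float form
                        str(h.align_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        repr(h.evalue),
                        repr(h.bitscore),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# protein catalog
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = ["protein_id", "aa_length", "description", "go_terms", "ec_codes", "tf_family"]


def read_catalog(path) -> dict[str, ProteinCatalogRecord]:
    rows = _tsv_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(path, 0, "empty file") from None
    _require_columns(header, _CATALOG_COLUMNS, path, header_lineno)
    idx = {col: header.index(col) for col in header}
    catalog: dict[str, ProteinCatalogRecord] = {}
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise FormatError(path, lineno, f"expected {len(header)} columns, got {len(fields)}")
        pid = fields[idx["protein_id"]]
        if pid in catalog:
            raise FormatError(path, lineno, f"duplicate protein_id {pid!r}")
        ec_codes = frozenset(e for e in fields[idx["ec_codes"]].split(";") if e)
        for ec in ec_codes:
            if not EC_PATTERN.match(ec):
                raise FormatError(path, lineno, f"malformed EC code {ec!r}")
        catalog[pid] = ProteinCatalogRecord(
            protein_id=pid,
            aa_length=_parse_int(fields[idx["aa_length"]], path, lineno, "aa_length", minimum=1),
            description=fields[idx["description"]],
            go_terms=frozenset(t for t in fields[idx["go_terms"]].split(";") if t),
            ec_codes=ec_codes,
            tf_family=fields[idx["tf_family"]] or None,
        )
    return catalog


def write_catalog(catalog: Mapping[str, ProteinCatalogRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for pid in sorted(catalog):
            p = catalog[pid]
            fh.write(
                "\t".join(
                    [
                        p.protein_id,
                        str(p.aa_length),
                        p.description,
                        ";".join(sorted(p.go_terms)),
                        ";".join(sorted(p.ec_codes)),
                        p.tf_family or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------


def _read_slim(slim_path) -> frozenset[str]:
    terms = []
    for _lineno, fields in _tsv_rows(slim_path):
        terms.append(fields[0])
    return frozenset(terms)


def read_ontology(path, slim_path=None, default_namespace="biological_process") -> OntologyBundle:
    """Read an ontology from restricted OBO 1.2 or a 3-column edge TSV.

    Edge-TSV columns: ``child``, ``parent``, ``relation``.  Terms seen only
    in the edge list get ``default_namespace`` and their id as name.  The
    graph restricted to is_a/part_of is checked for acyclicity; slim terms
    must exist in the ontology.
    """
    path = Path(path)
    namespace_of: dict[str, str] = {}
    name_of: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    if path.suffix == ".obo":
        graph = obonet.read_obo(path)
        for node, data in graph.nodes(data=True):
            namespace_of[node] = data.get("namespace", default_namespace)
            name_of[node] = data.get("name", node)
        for child, parent, rel in graph.edges(keys=True):
            edges.append((child, parent, rel))
    else:
        rows = _tsv_rows(path)
        try:
            header_lineno, header = next(rows)
        except StopIteration:
            raise FormatError(path, 0, "empty file") from None
        _require_columns(header, ["child", "parent", "relation"], path, header_lineno)
        idx = {col: header.index(col) for col in header}
        has_ns = "namespace" in header
        for lineno, fields in rows:
            if len(fields) != len(header):
                raise FormatError(path, lineno, f"expected {len(header)} columns, got {len(fields)}")
            child, parent, rel = fields[idx["child"]], fields[idx["parent"]], fields[idx["relation"]]
            if not child or not parent:
                raise FormatError(path, lineno, "empty child or parent id")
            ns = fields[idx["namespace"]] if has_ns else default_namespace
            for t in (child, parent):
                namespace_of.setdefault(t, ns)
                name_of.setdefault(t, t)
            edges.append((child, parent, rel))

    slim_set = _read_slim(slim_path) if slim_path is not None else frozenset()
    bundle = OntologyBundle(namespace_of, name_of, edges, slim_set)
    bundle.validate()
    return bundle


def write_ontology_edges(bundle: OntologyBundle, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("child\tparent\trelation\tnamespace\n")
        for child, parent, rel in sorted(bundle.edges):
            fh.write(f"{child}\t{parent}\t{rel}\t{bundle.namespace_of[child]}\n")


def write_obo(bundle: OntologyBundle, path) -> None:
    """Write a minimal OBO 1.2 file (id/name/namespace/is_a/relationship)."""
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in bundle.edges:
        by_child.setdefault(child, []).append((parent, rel))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(bundle.namespace_of):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {bundle.name_of[term]}\n")
            fh.write(f"namespace: {bundle.namespace_of[term]}\n")
            for parent, rel in sorted(by_child.get(term, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def write_slim(slim_set: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(slim_set):
            fh.write(term + "\n")


# ---------------------------------------------------------------------------
# gene -> term annotations, EC -> pathway map
# ---------------------------------------------------------------------------


def read_annotations(path) -> dict[str, set[str]]:
    """Read (protein_id, term_id) pairs into protein -> {terms}."""
    rows = _tsv_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(path, 0, "empty file") from None
    _require_columns(header, ["protein_id", "term_id"], path, header_lineno)
    idx = {col: header.index(col) for col in header}
    annotations: dict[str, set[str]] = {}
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise FormatError(path, lineno, f"expected {len(header)} columns, got {len(fields)}")
        annotations.setdefault(fields[idx["protein_id"]], set()).add(fields[idx["term_id"]])
    return annotations


def write_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tterm_id\n")
        for pid in sorted(annotations):
            for term in sorted(annotations[pid]):
                fh.write(f"{pid}\t{term}\n")


def read_ec_pathway_map(path) -> list[tuple[str, str]]:
    """Read (EC code, pathway name) pairs; malformed EC codes are fatal."""
    rows = _tsv_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(path, 0, "empty file") from None
    _require_columns(header, ["ec", "pathway"], path, header_lineno)
    idx = {col: header.index(col) for col in header}
    pairs = []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise FormatError(path, lineno, f"expected {len(header)} columns, got {len(fields)}")
        ec, pathway = fields[idx["ec"]], fields[idx["pathway"]]
        if not EC_PATTERN.match(ec):
            raise FormatError(path, lineno, f"malformed EC code {ec!r}")
        pairs.append((ec, pathway))
    return pairs


def write_ec_pathway_map(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ec\tpathway\n")
        for ec, pathway in pairs:
            fh.write(f"{ec}\t{pathway}\n")


# ---------------------------------------------------------------------------
# FASTA (synthetic reads, for realism only)
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")
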