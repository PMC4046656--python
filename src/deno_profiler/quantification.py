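"""Per-unigene read counting and protein-length RPKM.

A unigene is a cluster of isotigs annotated by the same reference
protein.  Because isoforms of one gene share contigs, and raw reads are
attached to contigs, a contig shared by several member isotigs must
contribute its reads exactly once: counting is a sum over the *set
union* of the members' contigs.  Without a reference genome there are
no exon models, so the RPKM feature length is the reference-protein
length in nucleotides (3 nt per residue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotation import UnigeneCluster
from .io_formats import AssemblyDataset

__all__ = ["ExpressionRecord", "dedup_count", "protein_nt_length", "rpkm", "build_expression_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """Deduplicated counts, RPKM and library sizes for one unigene."""

    unigene_id: str
    sample_ids: tuple[str, ...]
    raw_count: dict
    rpkm: dict
    library_size: dict
    protein_nt_length: int


def dedup_count(cluster: UnigeneCluster, assembly: AssemblyDataset, sample_id: str) -> int:
    """Reads of the unigene in one sample, each contig counted once.

    Sums the sample's read counts over the set union of the member
    isotigs' contigs, so a contig shared by several isoforms of the
    unigene contributes a single time.
    """
    if sample_id not in assembly.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    contig_union = set()
    for isotig_id in cluster.member_isotigs:
        if isotig_id not in assembly.isotigs:
            raise KeyError(f"unknown isotig {isotig_id!r} in cluster {cluster.unigene_id}")
        contig_union.update(assembly.isotigs[isotig_id].member_contigs)
    return sum(assembly.contigs[c].reads_per_sample[sample_id] for c in contig_union)


def protein_nt_length(aa_length: int) -> int:
    """Reference-protein length in nucleotides: 3 nt per residue, no stop codon."""
    if aa_length < 1:
        raise ValueError("aa_length must be >= 1")
    return 3 * aa_length


def rpkm(count: int, library_size: int, length_nt: int) -> float:
    """Reads per kilobase of feature length per million mapped reads.

    rpkm = 1e9 * C / (N * L) with C the raw count, N the library size
    and L the feature length in nucleotides.
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if length_nt < 1:
        raise ValueError("length_nt must be >= 1")
    if count < 0:
        raise ValueError("count must be >= 0")
    return 1e9 * count / (library_size * length_nt)


def build_expression_table(clusters: list[UnigeneCluster], assembly: AssemblyDataset) -> list[ExpressionRecord]:
    """One expression record per unigene, all samples populated.

    Library sizes are the total reads per sample across *all* contigs of
    the assembly, annotated or not.
    """
    if not clusters:
        log.warning("empty cluster list: expression table is empty")
        return []
    library = {s: assembly.library_size(s) for s in assembly.sample_ids}
    records = []
    for cluster in clusters:
        length_nt = protein_nt_length(cluster.protein.aa_length)
        counts = {s: dedup_count(cluster, assembly, s) for s in assembly.sample_ids}
        records.append(
            ExpressionRecord(
                unigene_id=cluster.unigene_id,
                sample_ids=assembly.sample_ids,
                raw_count=counts,
                rpkm={s: rpkm(counts[s], library[s], length_nt) for s in assembly.sample_ids},
                library_size=dict(library),
                protein_nt_length=length_nt,
            )
        )
    return records


def expression_frame(records: list[ExpressionRecord]):
    """Tabular view; RPKM columns are scaled x1000 (reporting convention)."""
    import pandas as pd

    if not records:
        return pd.DataFrame(columns=["unigene"])
    samples = records[0].sample_ids
    data = {"unigene": [r.unigene_id for r in records]}
    for s in samples:
        data[f"C_{s}"] = [r.raw_count[s] for r in records]
    for s in samples:
        data[f"RPKMx1000_{s}"] = [round(r.rpkm[s] * 1000, 2) for r in records]
    return pd.DataFrame(data)
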