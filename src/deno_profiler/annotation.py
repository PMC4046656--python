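"""E-value filtering, best-hit assignment and unigene clustering.

Function transfer from a reference protein to an isotig is only trusted
when the alignment E-value is *strictly below* the threshold (default
1e-20): the smaller the E-value, the higher the similarity and the
greater the confidence of the assignment.  Each isotig keeps a single
best annotator; isotigs annotated by the same reference protein form a
unigene, named after that protein.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import BlastHitRecord, ProteinCatalogRecord

__all__ = [
    "DEFAULT_EVALUE_THRESHOLD",
    "AnnotationAssignment",
    "UnigeneCluster",
    "filter_hits",
    "assign_best_hit",
    "cluster_unigenes",
]

DEFAULT_EVALUE_THRESHOLD = 1e-20


@dataclass(frozen=True)
class AnnotationAssignment:
    isotig_id: str
    protein_id: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class UnigeneCluster:
    """A reference protein plus the isotigs it annotates."""

    unigene_id: str  # equals the protein id
    protein: ProteinCatalogRecord
    member_isotigs: frozenset[str]

    def __post_init__(self):
        if not self.member_isotigs:
            raise ValueError(f"unigene {self.unigene_id}: empty isotig set")
        if self.unigene_id != self.protein.protein_id:
            raise ValueError(f"unigene id {self.unigene_id!r} != protein id {self.protein.protein_id!r}")


def filter_hits(hits: list[BlastHitRecord], evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD) -> list[BlastHitRecord]:
    """Keep exactly the hits with E-value strictly below the threshold.

    Input order is preserved; a hit at exactly the threshold is removed.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    return [h for h in hits if h.evalue < evalue_threshold]


def assign_best_hit(filtered_hits: list[BlastHitRecord]) -> list[AnnotationAssignment]:
    """One annotator per isotig: max bitscore, then min E-value, then protein id.

    The tie-break chain makes the assignment a total order, so the result
    is invariant under permutation of the input.  Isotigs without any
    surviving hit are simply absent (unannotated: candidate new genes).
    """
    best: dict[str, BlastHitRecord] = {}
    for hit in filtered_hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_key(hit) < _hit_key(cur):
            best[hit.query_id] = hit
    return [
        AnnotationAssignment(iso, h.subject_id, h.evalue, h.bitscore)
        for iso, h in sorted(best.items())
    ]


def _hit_key(hit: BlastHitRecord):
    # smaller is better: high bitscore, low evalue, lexicographic subject
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def cluster_unigenes(assignments: list[AnnotationAssignment], catalog: dict) -> list[UnigeneCluster]:
    """Group isotigs annotated by the same reference protein into unigenes.

    Clusters partition the annotated isotigs; assignment to a protein
    missing from the catalog is an error.
    """
    members: dict[str, set[str]] = {}
    for a in assignments:
        if a.protein_id not in catalog:
            raise KeyError(f"assignment to unknown protein {a.protein_id!r}")
        members.setdefault(a.protein_id, set()).add(a.isotig_id)
    return [
        UnigeneCluster(pid, catalog[pid], frozenset(isotigs))
        for pid, isotigs in sorted(members.items())
    ]
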