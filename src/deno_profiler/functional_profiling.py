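"""GO term-frequency profiles, slim rollup and EC -> pathway counting.

Term frequencies compare two gene sets (e.g. fruit-overexpressed vs
AZ-overexpressed unigenes) per ontology namespace; each gene contributes
at most once per term.  The slim rollup translates a specific term into
the coarse slim vocabulary by walking is_a/part_of ancestors: by default
a term maps to *all* reachable slim ancestors (nearest-only available).
Enzyme profiles count the distinct EC codes that differentially
expressed genes contribute to each metabolic pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

from .io_formats import EC_PATTERN, OntologyBundle, read_ec_pathway_map

__all__ = [
    "rollup_to_slim",
    "term_frequencies",
    "ec_pathway_profile",
    "ECPathwayProfile",
    "load_default_ec_pathway_map",
]


def rollup_to_slim(term: str, bundle: OntologyBundle, nearest_only: bool = False) -> set[str]:
    """Slim terms that are ancestors-or-self of ``term`` via is_a/part_of.

    With ``nearest_only`` the result keeps only the slim ancestors at the
    minimum edge distance from the term (self counts as distance 0).
    Returns the empty set when no slim term is reachable.
    """
    if term not in bundle.terms:
        raise KeyError(f"unknown ontology term {term!r}")
    graph = bundle.graph
    # graph edges run child -> parent, so ancestors are nx descendants
    reachable = {term} | nx.descendants(graph, term)
    hits = reachable & bundle.slim_set
    if not nearest_only or len(hits) <= 1:
        return hits
    dist = nx.single_source_shortest_path_length(graph, term)
    best = min(dist[t] for t in hits)
    return {t for t in hits if dist[t] == best}


def term_frequencies(
    gene_sets: dict[str, set[str]],
    annotations: dict[str, set[str]],
    bundle: OntologyBundle,
    use_slim: bool = False,
    nearest_only: bool = False,
) -> pd.DataFrame:
    """Occurrence counts per (namespace, term) for each named gene set.

    ``annotations`` maps gene -> GO terms (inherited from the annotating
    reference protein).  A gene contributes at most once per term even
    if several of its specific terms roll up to the same slim term.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for set_name, genes in gene_sets.items():
        for gene in genes:
            terms = annotations.get(gene, set())
            if use_slim:
                effective: set[str] = set()
                for t in terms:
                    if t in bundle.terms:
                        effective |= rollup_to_slim(t, bundle, nearest_only=nearest_only)
            else:
                effective = {t for t in terms if t in bundle.terms}
            for t in effective:
                key = (bundle.namespace_of[t], t)
                counts.setdefault(key, {})[set_name] = counts.get(key, {}).get(set_name, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["namespace", "term", "name", *gene_sets])
    rows = []
    for (ns, term), per_set in sorted(counts.items()):
        row = {"namespace": ns, "term": term, "name": bundle.name_of.get(term, term)}
        for set_name in gene_sets:
            row[set_name] = per_set.get(set_name, 0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ECPathwayProfile:
    """Distinct enzymes (EC codes) per pathway, sorted by enzyme count."""

    ec_sets: dict  # pathway -> frozenset of EC codes

    @property
    def enzyme_counts(self) -> dict:
        return {p: len(s) for p, s in self.ec_sets.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            ((p, len(s)) for p, s in self.ec_sets.items()),
            key=lambda item: (-item[1], item[0]),
        )
        return pd.DataFrame(rows, columns=["pathway", "enzyme_count"])


def ec_pathway_profile(deg_set: set[str], catalog: dict, ec_pathway_map: list[tuple[str, str]]) -> ECPathwayProfile:
    """Map the EC codes of differentially expressed genes onto pathways.

    ``deg_set`` holds unigene ids (= annotating protein ids).  Only the
    provided (EC, pathway) table links enzymes to pathways; each pathway
    collects the distinct EC codes contributed by the DEGs.
    """
    for ec, _pathway in ec_pathway_map:
        if not EC_PATTERN.match(ec):
            raise ValueError(f"malformed EC code {ec!r} in pathway map")
    deg_ecs: set[str] = set()
    for gene in deg_set:
        if gene in catalog:
            deg_ecs |= set(catalog[gene].ec_codes)
    ec_sets: dict[str, set[str]] = {}
    for ec, pathway in ec_pathway_map:
        if ec in deg_ecs:
            ec_sets.setdefault(pathway, set()).add(ec)
    return ECPathwayProfile({p: frozenset(s) for p, s in ec_sets.items()})


def load_default_ec_pathway_map() -> list[tuple[str, str]]:
    source = resources.files("deno_profiler.data").joinpath("ec2pathway.tsv")
    with resources.as_file(source) as path:
        return read_ec_pathway_map(path)
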