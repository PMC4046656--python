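"""Cluster labels (A1/A2/B1/B2/NS), Venn partition, TF-family catalog.

Significant unigenes fall on the side with the higher normalized
abundance (RPKM): side A is the first sample (fruit pericarp in the
olive study), side B the second (abscission zone).  Within a side, a
gene whose raw deduplicated count in the *other* tissue is exactly zero
is "exclusive" (A2/B2); otherwise it is "enriched" (A1/B1).
Non-significant genes are NS.  Transcription-factor family membership
is assigned by a priority-ordered keyword lexicon over the annotation
description.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .diffexp import DEResult
from .quantification import ExpressionRecord

__all__ = [
    "CLUSTER_LABELS",
    "TFLexicon",
    "TFCatalogEntry",
    "assign_cluster",
    "partition_summary",
    "classify_tf",
    "build_tf_catalog",
    "load_tf_lexicon",
    "load_reference_cluster_table",
    "classify_reference_rows",
]

CLUSTER_LABELS = ("A1", "A2", "B1", "B2", "NS")


def assign_cluster(de_result: DEResult, expression_record: ExpressionRecord) -> str:
    """Label one unigene by side (RPKM comparison) and exclusivity (count == 0)."""
    if de_result.unigene_id != expression_record.unigene_id:
        raise ValueError(
            f"mismatched records: {de_result.unigene_id!r} vs {expression_record.unigene_id!r}"
        )
    if not de_result.significant:
        return "NS"
    s1, s2 = expression_record.sample_ids
    r1, r2 = expression_record.rpkm[s1], expression_record.rpkm[s2]
    if r1 == r2:
        # impossible for a significant gene under the exact-test rule;
        # reaching this means the inputs are corrupt
        raise ValueError(
            f"unigene {de_result.unigene_id}: significant but identical RPKM in both samples"
        )
    if r1 > r2:
        return "A2" if expression_record.raw_count[s2] == 0 else "A1"
    return "B2" if expression_record.raw_count[s1] == 0 else "B1"


@dataclass(frozen=True)
class PartitionSummary:
    counts: dict
    side_a_total: int
    side_b_total: int
    venn_a_only: int  # exclusive on side A (A2)
    venn_b_only: int  # exclusive on side B (B2)
    venn_common: int  # expressed in both tissues (A1 + B1)


def partition_summary(labels: dict[str, str]) -> PartitionSummary:
    """Per-label counts and the Venn triple over expressed-in-tissue sets."""
    counts = {lab: 0 for lab in CLUSTER_LABELS}
    for lab in labels.values():
        if lab not in counts:
            raise ValueError(f"unknown cluster label {lab!r}")
        counts[lab] += 1
    return PartitionSummary(
        counts=counts,
        side_a_total=counts["A1"] + counts["A2"],
        side_b_total=counts["B1"] + counts["B2"],
        venn_a_only=counts["A2"],
        venn_b_only=counts["B2"],
        venn_common=counts["A1"] + counts["B1"],
    )


# ---------------------------------------------------------------------------
# transcription-factor lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFLexiconRule:
    priority: int
    pattern: re.Pattern
    family: str


class TFLexicon:
    """Priority-ordered keyword rules mapping descriptions to TF families."""

    def __init__(self, rules: list[TFLexiconRule]):
        priorities = [r.priority for r in rules]
        dupes = {p for p in priorities if priorities.count(p) > 1}
        if dupes:
            raise ValueError(
                f"lexicon rules with equal priority would make matching ambiguous: {sorted(dupes)}"
            )
        self.rules = sorted(rules, key=lambda r: r.priority)

    @property
    def families(self) -> list[str]:
        seen = []
        for r in self.rules:
            if r.family not in seen:
                seen.append(r.family)
        return seen

    def match(self, description: str) -> str | None:
        for rule in self.rules:
            if rule.pattern.search(description):
                return rule.family
        return None


def load_tf_lexicon(path=None) -> TFLexicon:
    """Load a lexicon TSV (priority, pattern, family); default is bundled."""
    if path is None:
        source = resources.files("deno_profiler.data").joinpath("tf_lexicon.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = open(path, encoding="utf-8").read()
    rules = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[:1] == ["priority"]:
            continue
        if len(fields) != 3:
            raise ValueError(f"tf lexicon line {lineno}: expected 3 columns, got {len(fields)}")
        priority, pattern, family = fields
        rules.append(TFLexiconRule(int(priority), re.compile(pattern, re.IGNORECASE), family))
    return TFLexicon(rules)


@dataclass(frozen=True)
class TFCatalogEntry:
    unigene_id: str
    family: str
    cluster: str


def classify_tf(unigene_id: str, catalog: dict, lexicon: TFLexicon) -> str | None:
    """TF family of a unigene's annotating protein, or None if not a TF."""
    protein = catalog[unigene_id]
    return lexicon.match(protein.description)


def build_tf_catalog(labels: dict[str, str], catalog: dict, lexicon: TFLexicon) -> list[TFCatalogEntry]:
    """TF entries for differentially expressed unigenes only."""
    entries = []
    for unigene_id in sorted(labels):
        if labels[unigene_id] == "NS":
            continue
        family = classify_tf(unigene_id, catalog, lexicon)
        if family is not None:
            entries.append(TFCatalogEntry(unigene_id, family, labels[unigene_id]))
    return entries


# ---------------------------------------------------------------------------
# bundled reference table (olive ripe-fruit pericarp vs abscission zone)
# ---------------------------------------------------------------------------


def load_reference_cluster_table():
    """The 100 most significant unigenes of the olive ripe-fruit pericarp
    vs abscission-zone comparison: RPKM x1000 in both tissues, p-value and
    published cluster label (25 per label)."""
    import pandas as pd

    source = resources.files("deno_profiler.data").joinpath("olive_top100_clusters.tsv")
    with resources.as_file(source) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def classify_reference_rows(table=None) -> "pd.DataFrame":  # noqa: F821
    """Re-derive the cluster label of each bundled reference row.

    The table prints normalized abundances (RPKM x1000) and p-values; a
    printed abundance of exactly 0.00 denotes zero raw reads in that
    tissue, so exclusivity can be recovered from the table alone.
    """
    if table is None:
        table = load_reference_cluster_table()
    assigned = []
    for row in table.itertuples(index=False):
        rec = ExpressionRecord(
            unigene_id=row.unigene,
            sample_ids=("fruit", "az"),
            raw_count={"fruit": 0 if row.rpkm1000_fruit == 0 else 1,
                       "az": 0 if row.rpkm1000_az == 0 else 1},
            rpkm={"fruit": row.rpkm1000_fruit, "az": row.rpkm1000_az},
            library_size={"fruit": 1, "az": 1},
            protein_nt_length=3,
        )
        de = DEResult(row.unigene, (rec.raw_count["fruit"], rec.raw_count["az"]),
                      0.0, float(row.pvalue), float(row.pvalue) < 0.01)
        assigned.append(assign_cluster(de, rec))
    out = table.copy()
    out["assigned_label"] = assigned
    return out
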