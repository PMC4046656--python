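import math

import numpy as np
import pytest

from deno_profiler.annotation import assign_best_hit, cluster_unigenes, filter_hits
from deno_profiler.diffexp import DEResult, NBModelParams, run_de
from deno_profiler.quantification import build_expression_table
from deno_profiler.synthetic_data import (
    GeneTruth,
    SimConfig,
    TruthManifest,
    simulate_dataset,
    truth_eval,
    write_dataset,
)


def _de_pipeline(sim, phi):
    clusters = cluster_unigenes(assign_best_hit(filter_hits(sim.hits)), sim.catalog)
    expression = build_expression_table(clusters, sim.assembly)
    return run_de(expression, NBModelParams(phi=phi))


def test_same_seed_gives_byte_identical_datasets(tmp_path):
    cfg = SimConfig(n_genes=30, seed=42)
    for run in ("one", "two"):
        write_dataset(simulate_dataset(cfg), tmp_path / run)
    for name in ("contigs.tsv", "isotigs.tsv", "hits.tsv", "catalog.tsv",
                 "ontology_edges.tsv", "slim.txt", "annotations.tsv", "truth.tsv"):
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


def test_adding_genes_does_not_reshuffle_earlier_draws():
    """Per-gene substreams: enlarging n_genes leaves the structure, catalog
    and hit draws of earlier genes untouched (counts shift only through
    the global abundance normalization)."""
    small = simulate_dataset(SimConfig(n_genes=20, seed=5, de_fraction=0.0))
    large = simulate_dataset(SimConfig(n_genes=40, seed=5, de_fraction=0.0))
    for cid, contig in small.assembly.contigs.items():
        assert large.assembly.contigs[cid].length_nt == contig.length_nt
    assert all(large.assembly.isotigs[i] == iso for i, iso in small.assembly.isotigs.items())
    assert all(large.catalog[p] == rec for p, rec in small.catalog.items())
    # true hits (below the E-value threshold) are reproduced; decoy targets
    # are drawn over the full gene range and may legitimately differ
    def true_hits(sim):
        return {h.query_id: h for h in sim.hits if h.evalue < 1e-20}

    small_true, large_true = true_hits(small), true_hits(large)
    assert all(large_true[k] == h for k, h in small_true.items())
    small_p = {g.protein_id for g in small.manifest.genes}
    assert small_p <= {g.protein_id for g in large.manifest.genes}


def test_zero_de_fraction_means_all_null():
    sim = simulate_dataset(SimConfig(n_genes=50, seed=1, de_fraction=0.0))
    assert all(not g.is_de and g.true_logfc == 0.0 for g in sim.manifest.genes)


def test_abundances_sum_to_one_per_sample(sim_small):
    for s in sim_small.manifest.sample_ids:
        assert math.isclose(sum(g.p[s] for g in sim_small.manifest.genes), 1.0, rel_tol=1e-9)


def test_library_totals_equal_contig_sums(sim_small):
    for s in sim_small.assembly.sample_ids:
        total = sum(c.reads_per_sample[s] for c in sim_small.assembly.contigs.values())
        assert sim_small.assembly.library_size(s) == total


def test_unigene_counts_recover_gene_level_draws(sim_small):
    """Dedup counting over the gene's isotigs returns the gene-level draw,
    so the per-sample totals over unigenes equal the library sizes."""
    clusters = cluster_unigenes(assign_best_hit(filter_hits(sim_small.hits)), sim_small.catalog)
    expression = build_expression_table(clusters, sim_small.assembly)
    for s in sim_small.assembly.sample_ids:
        assert sum(r.raw_count[s] for r in expression) == sim_small.assembly.library_size(s)


def test_poisson_case_has_unit_dispersion():
    """At phi=0 counts are Poisson: the mean of (y1-y2)^2/(y1+y2) over null
    genes with balanced libraries is ~1 (conditional dispersion statistic)."""
    cfg = SimConfig(n_genes=200, seed=9, de_fraction=0.0, phi=0.0,
                    library_sizes=(100000, 100000))
    sim = simulate_dataset(cfg)
    by_gene = sim.manifest.genes
    stats = []
    for g in by_gene:
        y = [sum(sim.assembly.contigs[c].reads_per_sample[s] for c in g.contigs)
             for s in sim.manifest.sample_ids]
        if y[0] + y[1] > 0:
            stats.append((y[0] - y[1]) ** 2 / (y[0] + y[1]))
    assert abs(np.mean(stats) - 1.0) < 0.3  # MC tolerance ~ sqrt(2/200) * 3


def test_exclusive_genes_have_zero_reads_in_off_tissue():
    cfg = SimConfig(n_genes=60, seed=2, phi=0.0, de_fraction=0.5, exclusive_fraction=1.0)
    sim = simulate_dataset(cfg)
    s1, s2 = sim.manifest.sample_ids
    excl = [g for g in sim.manifest.genes if g.is_exclusive]
    assert excl
    for g in excl:
        off = s2 if g.true_logfc > 0 else s1
        assert g.p[off] == 0.0
        assert sum(sim.assembly.contigs[c].reads_per_sample[off] for c in g.contigs) == 0


def test_stronger_effects_increase_estimated_logfc():
    means = []
    for effect in (1.0, 2.0, 3.0):
        cfg = SimConfig(n_genes=60, seed=21, de_fraction=0.3, exclusive_fraction=0.0,
                        logfc_effect=effect, library_sizes=(50000, 50000))
        sim = simulate_dataset(cfg)
        de = {g.protein_id for g in sim.manifest.genes if g.is_de}
        results = _de_pipeline(sim, phi=0.1)
        means.append(np.mean([abs(r.logfc) for r in results if r.unigene_id in de]))
    assert means[0] <= means[1] <= means[2]


def test_infeasible_config_is_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_genes=0)
    with pytest.raises(ValueError):
        SimConfig(de_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(library_sizes=(0, 10))


# ---------------------------------------------------------------------------
# truth_eval
# ---------------------------------------------------------------------------


def _manifest(n_de, n_null):
    genes = []
    for i in range(n_de + n_null):
        is_de = i < n_de
        genes.append(GeneTruth(f"P{i:05d}", {"fruit": 0.5, "az": 0.5},
                               2.0 if is_de else 0.0, is_de, False, ("i",), ("c",)))
    return TruthManifest(("fruit", "az"), genes)


def _results(manifest, flag):
    return [
        DEResult(g.protein_id, (1, 1), g.true_logfc, 0.0 if flag(g) else 1.0, flag(g))
        for g in manifest.genes
    ]


def test_perfect_caller_has_no_errors():
    manifest = _manifest(4, 6)
    summary = truth_eval(_results(manifest, lambda g: g.is_de), manifest)
    assert (summary.tp, summary.fp, summary.fn, summary.tn) == (4, 0, 0, 6)
    assert summary.logfc_bias == 0.0 and summary.logfc_rmse == 0.0


def test_silent_caller_misses_all_de_genes():
    manifest = _manifest(4, 6)
    summary = truth_eval(_results(manifest, lambda g: False), manifest)
    assert summary.tp == 0 and summary.fn == 4


def test_random_caller_false_positive_rate_is_binomial():
    rate = 0.3
    manifest = _manifest(0, 500)
    rng = np.random.default_rng(7)
    flags = {g.protein_id: bool(rng.random() < rate) for g in manifest.genes}
    summary = truth_eval(_results(manifest, lambda g: flags[g.protein_id]), manifest)
    # binomial oracle: 4 sigma band around the flip rate
    assert abs(summary.fpr - rate) < 4 * math.sqrt(rate * (1 - rate) / 500)


def test_truth_eval_rejects_id_mismatch():
    manifest = _manifest(1, 1)
    results = _results(manifest, lambda g: False)[:1]
    with pytest.raises(ValueError, match="mismatch"):
        truth_eval(results, manifest)
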