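import numpy as np
import pytest

from deno_profiler.io_formats import (
    AssemblyDataset,
    ContigRecord,
    IsotigRecord,
    OntologyBundle,
    ProteinCatalogRecord,
)
from deno_profiler.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def small_assembly():
    """Three contigs, two isotigs sharing contig c2, two samples."""
    contigs = {
        "c1": ContigRecord("c1", 300, {"fruit": 5, "az": 1}),
        "c2": ContigRecord("c2", 500, {"fruit": 7, "az": 2}),
        "c3": ContigRecord("c3", 400, {"fruit": 3, "az": 0}),
    }
    isotigs = {
        "i1": IsotigRecord("i1", ("c1", "c2")),
        "i2": IsotigRecord("i2", ("c2", "c3")),
    }
    return AssemblyDataset(("fruit", "az"), contigs, isotigs)


@pytest.fixture
def small_catalog():
    return {
        "P1": ProteinCatalogRecord("P1", 250, "Beta-glucosidase"),
        "P2": ProteinCatalogRecord("P2", 100, "NAC domain protein, SlNAC1"),
    }


@pytest.fixture
def chain_ontology():
    """t -> a -> b -> root, all is_a, slim = {b}."""
    terms = {t: "biological_process" for t in ("t", "a", "b", "root")}
    edges = [("t", "a", "is_a"), ("a", "b", "is_a"), ("b", "root", "is_a")]
    return OntologyBundle(terms, {t: t for t in terms}, edges, frozenset({"b"}))


@pytest.fixture(scope="session")
def sim_small():
    return simulate_dataset(SimConfig(n_genes=40, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
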