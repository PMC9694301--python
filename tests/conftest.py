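"""Shared offline fixtures: synthetic stores, corpora and wired CLI roots."""

import pytest

from seqharvest import fixtures as fx
from seqharvest.resolver import FixtureMetadataBackend


@pytest.fixture(scope="session")
def store(tmp_path_factory):
    """A two-study archive with payload: GEO series, BioProjects, samples."""
    root = tmp_path_factory.mktemp("store")
    result = fx.make_store(
        fx.StoreSpec(seed=11, n_studies=2, runs_per_study=(3, 5)), root
    )
    fx.write_store(result, root)
    return result


@pytest.fixture(scope="session")
def backend(store):
    return FixtureMetadataBackend(store.tree)


@pytest.fixture(scope="session")
def corpus():
    """Ten synthetic articles with known embedded accession sets."""
    return fx.make_corpus(fx.CorpusSpec(seed=7, n_articles=10))


@pytest.fixture()
def pipeline_root(tmp_path):
    """A fixture-backend root: metadata.json + store/ + articles/ wired together.

    Articles cite accessions that the metadata tree can resolve, so the whole
    mine -> resolve -> download pipeline runs offline.
    """
    result = fx.make_store(
        fx.StoreSpec(seed=23, n_studies=2, runs_per_study=(2, 3)), tmp_path
    )
    fx.write_store(result, tmp_path)
    pool = tuple(result.series_map) + tuple(result.project_map)
    corpus = fx.make_corpus(
        fx.CorpusSpec(
            seed=23, n_articles=3, accessions_per_article=(1, 2), accession_pool=pool
        )
    )
    fx.write_corpus(corpus, tmp_path / "articles")
    return {"root": tmp_path, "store": result, "corpus": corpus}
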