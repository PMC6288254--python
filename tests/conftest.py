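import pytest

from kirsplice import fixtures
from kirsplice.cli import RunConfig, run_pipeline
from kirsplice.genemodel import build_catalog_models, build_fixture_model

SEED = 1


@pytest.fixture(scope="session")
def human_catalog():
    return fixtures.human_catalog()


@pytest.fixture(scope="session")
def macaque_catalog():
    return fixtures.macaque_catalog()


@pytest.fixture(scope="session")
def human_models(human_catalog):
    return build_catalog_models(human_catalog, SEED)


@pytest.fixture(scope="session")
def macaque_models(macaque_catalog):
    return build_catalog_models(macaque_catalog, SEED)


@pytest.fixture(scope="session")
def model_of(human_models, macaque_models):
    by_key = {m.key: m for m in human_models + macaque_models}
    return by_key.__getitem__


@pytest.fixture(scope="session")
def human_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("human_run")
    return run_pipeline(RunConfig(catalog="human", cohort="human_table1",
                                  seed=SEED, out_dir=str(out)))


@pytest.fixture(scope="session")
def macaque_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("macaque_run")
    return run_pipeline(RunConfig(catalog="macaque", cohort="macaque_table2",
                                  seed=SEED, out_dir=str(out)))


@pytest.fixture(scope="session")
def figure7_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("figure7_run")
    return run_pipeline(RunConfig(catalog="macaque", cohort="kir1d_figure7",
                                  seed=SEED, out_dir=str(out)))


@pytest.fixture(scope="session")
def toy_entry():
    """A small (~2.6 kb) gene for dynamic-programming oracle comparisons."""
    from kirsplice.genemodel import ALT3_DEL, CRYPTIC, AlleleEntry, Feature
    return AlleleEntry(
        gene_id="TOY", allele_id="001", lineage="III",
        exon_lengths=(34, 36, 120, 150, 141, 51, 105, 53, 150),
        intron_lengths=(100,) * 8,
        features=(
            Feature("del30", ALT3_DEL, 5, 30, frame="in"),
            Feature("cryp30", CRYPTIC, 6, 30, offset_bp=20, frame="stop"),
        ),
        attributes={"purine_element": False},
        validated_isoforms=(((), "in"), (("skip:6",), "in")),
    )


@pytest.fixture(scope="session")
def toy_model(toy_entry):
    return build_fixture_model(toy_entry, SEED)
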