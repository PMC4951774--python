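import pytest

from etglink.ontology import GOAnnotationTable, GODag, compute_ic
from etglink.pipeline import bundle_feature_table, load_bundle
from etglink.simulate import FixtureConfig, generate


@pytest.fixture(scope="session")
def toy_dag():
    """Three-level DAG with propagated counts 8 / 4 / 1.

    root -> mid -> two sibling leaves; eight genes total, four at or below
    mid, one per leaf.  Gives IC 0 / ln 2 / ln 8 and Lin(leaf1, leaf2) = 1/3.
    """
    parents = {
        "root": frozenset(),
        "mid": frozenset({"root"}),
        "leaf1": frozenset({"mid"}),
        "leaf2": frozenset({"mid"}),
    }
    namespace = {t: "biological_process" for t in parents}
    dag = GODag(parents, namespace)
    ann = GOAnnotationTable(
        {
            "g1": frozenset({"leaf1"}),
            "g2": frozenset({"leaf2"}),
            "g3": frozenset({"mid"}),
            "g4": frozenset({"mid"}),
            "g5": frozenset({"root"}),
            "g6": frozenset({"root"}),
            "g7": frozenset({"root"}),
            "g8": frozenset({"root"}),
        }
    )
    compute_ic(dag, ann)
    return dag, ann


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic fixture (seed 1), generated once per session."""
    outdir = tmp_path_factory.mktemp("fixture_default")
    return generate(FixtureConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def default_table(default_bundle):
    """Labelled feature table of the default fixture."""
    bundle = load_bundle(default_bundle.outdir)
    return bundle_feature_table(bundle)


@pytest.fixture(scope="session")
def null_bundle(tmp_path_factory):
    """Zero-effect fixture: labels exchangeable, >= 2000 pairs (seed 11)."""
    outdir = tmp_path_factory.mktemp("fixture_null")
    cfg = FixtureConfig(n_enhancers=160, seed=11).zero_effects()
    return generate(cfg, outdir)
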