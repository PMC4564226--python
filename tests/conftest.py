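import numpy as np
import pytest

from genegravity import netio, synthdata


@pytest.fixture(scope="session")
def small_study():
    """One shared small synthetic study (seeded, deterministic)."""
    return synthdata.synth_study("small", seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """The small study pushed through CePIN, propagation and gravity."""
    import genegravity as gg

    filtered, _ = gg.filter_expression(small_study.expression)
    cepin = gg.build_cepin(small_study.network, filtered)
    m0 = gg.build_m0(small_study.mutations, small_study.network)
    prop = gg.propagate(small_study.network, m0)
    table = gg.pairwise_gravity(cepin, prop)
    scores = gg.aveg_scores(
        table, metadata=small_study.metadata, degrees=small_study.network.degrees
    )
    return {
        "study": small_study,
        "cepin": cepin,
        "m0": m0,
        "prop": prop,
        "gravity": table,
        "scores": scores,
    }


@pytest.fixture
def path_graph():
    """A-B-C path network."""
    return netio.load_interactions([("A", "B"), ("B", "C")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
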