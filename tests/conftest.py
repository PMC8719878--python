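import numpy as np
import pytest

from allofit import (
    ConstructAnnotation,
    SyntheticSpec,
    build_ledger,
    generate_panel,
    rescale_activity,
)
from allofit import reference as ref
from allofit.ledger import DEFAULT_BOUNDS


@pytest.fixture(scope="session")
def mini_annotations():
    """Five-construct subset exercising every slot scope."""
    return (
        ConstructAnnotation("Y60C"),
        ConstructAnnotation("Y60C TM7", insertions=((219, 7),)),
        ConstructAnnotation("Y60C HAMP 7", insertions=((260, 7),), localize=("k_hamp",)),
        ConstructAnnotation("E232A", mutations=(232,), localize=("alpha2",)),
        ConstructAnnotation("Y265A", mutations=(265,)),
    )


@pytest.fixture(scope="session")
def mini_ledger(mini_annotations):
    return build_ledger(mini_annotations, model="three_domain")


@pytest.fixture(scope="session")
def mini_values(mini_ledger):
    """Published values resolved onto the mini ledger's slots."""
    return ref.reference_slot_values(mini_ledger)


@pytest.fixture(scope="session")
def mini_replicates():
    return {"Y60C": 3, "Y60C TM7": 1, "Y60C HAMP 7": 2, "E232A": 2, "Y265A": 1}


@pytest.fixture
def make_mini_panel(mini_ledger, mini_values, mini_replicates):
    """Factory for rescaled mini panels at configurable noise."""

    def _make(seed=11, noise_xl=0.0, noise_act=0.0, q_nominal=1000.0, rescale=True):
        spec = SyntheticSpec(
            ledger=mini_ledger,
            true_values=mini_values,
            seed=seed,
            replicate_counts=mini_replicates,
            noise_sd_crosslink=noise_xl,
            noise_sd_activity_rel=noise_act,
            q_nominal=q_nominal,
        )
        panel = generate_panel(spec)
        if rescale:
            panel = rescale_activity(panel, q=q_nominal)
        return spec, panel

    return _make


@pytest.fixture(scope="session")
def bounds_box_draws():
    """1,000 random three-domain parameter draws spanning the bounds box."""
    rng = np.random.default_rng(2024)
    roles = ("k_sen", "k_hamp", "k_ak", "alpha1", "alpha2", "s", "kd_off", "kd_on")
    draws = []
    for _ in range(1000):
        values = {}
        for role in roles:
            lo, hi = DEFAULT_BOUNDS[role]
            values[role] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        draws.append(values)
    return draws
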