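import pytest

from hjkit.combinatorics import enumerate_immobile_classes
from hjkit.synth import IonPlan, SynthSpec, build_junction, build_trajectory


@pytest.fixture(scope="session")
def immobile_classes():
    return enumerate_immobile_classes()


@pytest.fixture(scope="session")
def quartet(immobile_classes):
    """Canonical quartet of the first immobile class, used as default fixture."""
    return immobile_classes[0].canonical.refs


@pytest.fixture()
def junction_60(quartet):
    """Ideal right-handed stacked-X junction at 60 deg, zero noise."""
    spec = SynthSpec.from_quartet(quartet, arm_length=8, angle=60.0,
                                  handedness="right")
    return build_junction(spec)


@pytest.fixture()
def make_trajectory(quartet):
    """Factory for synthetic trajectories with a single planted ion."""

    def _make(bound_frames=frozenset(range(53)), n_frames=100, angle=55.0,
              noise=0.3, seed=11, site="Pos1", ion=True):
        plans = (IonPlan(frames=frozenset(bound_frames), site=site),) if ion else ()
        spec = SynthSpec.from_quartet(
            "AACC", arm_length=8, angle=angle, noise_sigma=noise,
            n_frames=n_frames, ion_plans=plans, seed=seed,
        )
        return build_trajectory(spec)

    return _make
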