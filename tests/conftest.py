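import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moreba.core import FACTORS, moreba_score
from moreba.simulate import PopulationSpec, generate_cmdq, generate_profiles

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def big_cohort():
    """One large synthetic cohort (n=10000, fixed seed), shared by the
    fidelity and calibration tests to keep the suite fast."""
    spec = PopulationSpec(n=10_000, seed=0)
    profiles = generate_profiles(spec)
    totals = generate_cmdq(profiles, spec=spec)
    factor_matrix = np.array(
        [[p.factor_values()[f] for f in FACTORS] for p in profiles]
    )
    scores = np.array([moreba_score(p) for p in profiles])
    return {
        "spec": spec,
        "profiles": profiles,
        "totals": totals,
        "factors": factor_matrix,
        "scores": scores,
    }


def auc_brute_force(scores, labels):
    """Exhaustive pairwise AUC oracle: mean over all (positive, negative)
    pairs of 1 / 0.5 / 0 for win / tie / loss."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
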