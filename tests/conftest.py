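import pytest
from hypothesis import HealthCheck, settings

import corticospinal as cs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return cs.make_design()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Tiny noiseless cohort — exact-recovery fixture."""
    dist = cs.TruthDistribution(noise_sd=0.0)
    return cs.simulate_cohort(n_participants=4, distribution=dist, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-conditions cohort (n=13, noise 0.3)."""
    return cs.simulate_cohort(seed=23)


@pytest.fixture(scope="session")
def small_cohort_tables(small_cohort):
    betas = cs.cohort_betas(small_cohort)
    estimates = cs.cohort_connectivity(small_cohort)
    return small_cohort, betas, estimates


def random_beta_table(rng, n_subjects=13, effects=None):
    """Random fully-crossed 2x2x2 within-subject SHc beta table."""
    import pandas as pd

    from corticospinal.design import HANDS, contra_shc, ipsi_shc

    effects = effects or {}
    rows = []
    for s in range(n_subjects):
        pid = f"sub-{s:02d}"
        subj_off = rng.normal(0, 0.3)
        for hand in HANDS:
            for segment in ("C5", "C7Th1"):
                for side, fn in (("ipsi", ipsi_shc), ("contra", contra_shc)):
                    val = subj_off + rng.normal(0, 1.0)
                    val += effects.get("segment", 0.0) * (segment == "C7Th1")
                    val += effects.get("side", 0.0) * (side == "ipsi")
                    val += effects.get("hand", 0.0) * (hand == "RHM")
                    val += (
                        effects.get("side_hand", 0.0)
                        * (side == "ipsi")
                        * (hand == "RHM")
                    )
                    rows.append(
                        {
                            "participant_id": pid,
                            "region": fn(hand, segment),
                            "hand": hand,
                            "beta": val,
                        }
                    )
    return pd.DataFrame(rows)
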