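import pytest
from hypothesis import HealthCheck, settings

import retroclock as rc

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def recovery_run():
    """Fixed-seed end-to-end recovery experiment: 600 samples, 3000 probes,
    150 causal CpGs with a logit-linear age effect; identity transform."""
    beta, meta, causal = rc.simulate_methylation_cohort(rc.SyntheticConfig(seed=11))
    result = rc.train_clock(
        beta, meta, rc.AgeTransform("identity"), rc.TrainingConfig(seed=11)
    )
    return {"beta": beta, "meta": meta, "causal": set(causal), "result": result}


@pytest.fixture(scope="session")
def multispecies_run():
    """Multi-species, multi-tissue cohort driven by relative age
    ln(age + 2), trained with the log-offset transform under a
    donor-grouped split."""
    cfg = rc.SyntheticConfig(
        n_samples=400, n_probes=1500, n_causal=100,
        n_donors=200, n_tissues=2, n_species=8, seed=7,
    )
    beta, meta, causal = rc.simulate_methylation_cohort(cfg)
    result = rc.train_clock(
        beta, meta, rc.AgeTransform("log_offset", 2.0),
        rc.TrainingConfig(seed=7, group_by_donor=True),
    )
    return {"beta": beta, "meta": meta, "causal": set(causal), "result": result}
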