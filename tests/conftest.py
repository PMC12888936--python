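import numpy as np
import pytest

from iolopt import BiometryRecord, Cohort, FormulaConstants, FormulaId, preset_config, generate


@pytest.fixture
def toy_record():
    return BiometryRecord(
        eye_id="toy", al=23.5, acd=3.2, lt=4.6, r1=7.7, r2=7.7, iolp=21.0, seq_achieved=-0.25
    )


def make_random_records(n, seed, with_outcome=True):
    """Random plausible eyes (uniform over a comfortable clinical range)."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        recs.append(
            BiometryRecord(
                eye_id=f"e{i:04d}",
                al=rng.uniform(20.5, 28.5),
                acd=rng.uniform(2.4, 4.2),
                lt=rng.uniform(3.8, 5.4),
                r1=rng.uniform(7.2, 8.4),
                r2=rng.uniform(7.0, 8.2),
                iolp=rng.uniform(8.0, 30.0),
                seq_achieved=rng.uniform(-3.0, 1.0) if with_outcome else 0.0,
            )
        )
    return recs


@pytest.fixture
def random_cohort():
    return Cohort(records=make_random_records(50, seed=123), label="random-50")


@pytest.fixture(scope="session")
def dataset1_cohort():
    """Synthetic dataset-1 style cohort (SRK/T truth, 0.42 D noise), fixed seed."""
    cohort, truth = generate(preset_config(1, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def small_synth_cohort():
    """Small cohort (n=100) for optimizer-vs-grid comparisons."""
    cohort, truth = generate(preset_config(1, n=100, seed=42))
    return cohort, truth
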