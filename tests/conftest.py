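import numpy as np
import pandas as pd
import pytest

from tcd.features import FEATURE_NAMES, FeatureTable
from tcd.synth import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def params_60s() -> GeneratorParams:
    return GeneratorParams(duration_s=60.0)


@pytest.fixture(scope="session")
def cohort20(params_60s):
    """20 subjects per group, 60 s records — the desk-scale study cohort."""
    counts = {g: 20 for g in ("healthy", "tinnitus", "pain", "parkinson", "depression")}
    return generate_cohort(counts, params_60s, master_seed=7)


@pytest.fixture(scope="session")
def table20(cohort20):
    from tcd.features import build_feature_table

    return build_feature_table(cohort20)


@pytest.fixture(scope="session")
def small_cohort(params_60s):
    """8 healthy + 8 tinnitus subjects, 60 s records."""
    return generate_cohort({"healthy": 8, "tinnitus": 8}, params_60s, master_seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    from tcd.features import build_feature_table

    return build_feature_table(small_cohort)


@pytest.fixture
def make_gaussian_table():
    """Feature tables of pure Gaussian noise (no class signal) for calibration tests."""

    def _make(counts: dict[str, int], seed: int = 0, effect: float = 0.0) -> FeatureTable:
        rng = np.random.default_rng(seed)
        labels = [g for g, n in counts.items() for _ in range(n)]
        X = rng.standard_normal((len(labels), len(FEATURE_NAMES)))
        if effect:
            mask = np.array([l != "healthy" for l in labels], dtype=float)
            X[:, :10] += effect * mask[:, None]
        idx = pd.Index([f"s{i:03d}" for i in range(len(labels))], name="subject_id")
        data = pd.DataFrame(X, index=idx, columns=FEATURE_NAMES)
        return FeatureTable(data, pd.Series(labels, index=idx, name="group"))

    return _make
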