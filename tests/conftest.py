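import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from precsel.data_model import Feature, FeatureMap

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_feature(fid, profile, mz=1000.0, rt_per_bin=30.0):
    lo, hi = min(profile), max(profile)
    return Feature(
        feature_id=fid,
        mz=mz,
        intensity_profile=dict(profile),
        rt_min=lo * rt_per_bin,
        rt_max=(hi + 1) * rt_per_bin,
    )


def make_map(features, n_fractions, cap=2, bin_width=30.0):
    return FeatureMap(
        features=tuple(features),
        n_fractions=n_fractions,
        fraction_rt={s: (s + 0.5) * bin_width for s in range(n_fractions)},
        capacities={s: cap for s in range(n_fractions)},
    )


def sps_equivalence_map(seed=2025):
    """Fixed 200-feature map for the feature-only reduction check.

    40 fractions at capacity 25 with round-robin feature starts and spans
    of at most 3, so no fraction is covered by more than 15 features and
    the capacity rows can never force a feature off its best fraction.
    Under that condition the budgeted feature ILP optimum provably equals
    the intensity-ranked greedy prefix.
    """
    rng = np.random.default_rng(seed)
    n_fractions = 40
    feats = []
    for i in range(200):
        start = i % n_fractions
        span = int(rng.integers(1, 4))
        span = min(span, n_fractions - start)
        vals = rng.uniform(10.0, 1000.0, size=span)
        profile = {start + k: float(v) for k, v in enumerate(vals)}
        feats.append(make_feature(f"f{i:03d}", profile, mz=400.0 + 7.0 * i))
    return make_map(feats, n_fractions=n_fractions, cap=25)


@pytest.fixture
def figure1_map():
    """Worked four-feature / three-spectra example, capacity 2 per spectrum.

    Constructed so that DDA (top-2 per spectrum) never selects the
    low-intensity feature c, the greedy approach selects three features
    with none in spectrum S3, and the globally optimal ILP selects all
    four features once.
    """
    feats = [
        make_feature("a", {0: 100.0, 1: 80.0, 2: 65.0}),
        make_feature("b", {0: 90.0, 1: 70.0}),
        make_feature("c", {0: 50.0, 1: 40.0, 2: 30.0}),
        make_feature("d", {1: 85.0, 2: 60.0}),
    ]
    return make_map(feats, n_fractions=3, cap=2)


def random_map(rng: np.random.Generator, n_features=8, n_fractions=4, cap=2,
               max_span=3, grid=1000):
    """Random map with normalized intensities on a 1/grid lattice.

    Each feature's maximum is exactly 1.0 so intensities are already
    normalized; lattice values make independently computed objective sums
    exactly comparable.
    """
    feats = []
    for i in range(n_features):
        span = int(rng.integers(1, min(max_span, n_fractions) + 1))
        start = int(rng.integers(0, max(1, n_fractions - span + 1)))
        vals = rng.integers(1, grid, size=span).astype(float) / grid
        vals[rng.integers(span)] = 1.0
        profile = {start + k: float(v) for k, v in enumerate(vals)}
        feats.append(make_feature(f"f{i:03d}", profile, mz=500.0 + 10.0 * i))
    return make_map(feats, n_fractions=n_fractions, cap=cap)
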