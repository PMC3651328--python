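"""Reference precursor-selection strategies.

Four strategies the optimization-based methods are compared against:

* DDA — data-dependent acquisition: in each spectrum independently, the
  cap_s most intense signals are fragmented.  A feature eluting over
  several fractions can be fragmented repeatedly (the redundancy the
  optimized methods avoid).
* DEX — DDA with dynamic exclusion: an m/z fragmented in one of the
  previous ``exclusion_span`` fractions is skipped; the freed slot is
  refilled with the next most intense eligible signal.
* GA — greedy feature-based selection: each feature is assigned to its
  highest-intensity fraction, then each fraction keeps its cap_s most
  intense assigned features.
* SPS — static precursor selection: a fixed intensity-sorted inclusion
  list, consumed in rank order, each feature scheduled into its best
  still-available fraction.

All strategies break intensity ties by (earlier fraction, lexicographic
feature id), making every output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_model import Feature, FeatureMap

__all__ = [
    "SelectionResult",
    "select_dda",
    "select_dex",
    "select_greedy",
    "select_sps",
    "sps_ranking",
]


@dataclass
class SelectionResult:
    """Ordered list of (feature_id, fraction) precursors plus per-fraction tallies."""

    selected: list[tuple[str, int]] = field(default_factory=list)
    per_fraction_counts: dict[int, int] = field(default_factory=dict)

    def add(self, feature_id: str, fraction: int) -> None:
        self.selected.append((feature_id, fraction))
        self.per_fraction_counts[fraction] = self.per_fraction_counts.get(fraction, 0) + 1

    @property
    def unique_features(self) -> set[str]:
        return {fid for fid, _ in self.selected}

    def count_in(self, fraction: int) -> int:
        return self.per_fraction_counts.get(fraction, 0)


def _by_intensity(features: list[tuple[float, str]]) -> list[str]:
    """Sort feature ids by intensity descending, ties by id."""
    return [fid for _, fid in sorted(features, key=lambda t: (-t[0], t[1]))]


def select_dda(fmap: FeatureMap) -> SelectionResult:
    """Top-cap_s most intense signals in each spectrum, independently per spectrum."""
    result = SelectionResult()
    for s in range(fmap.n_fractions):
        candidates = [
            (f.intensity(s), f.feature_id)
            for f in fmap.features
            if s in f.intensity_profile
        ]
        for fid in _by_intensity(candidates)[: fmap.capacity(s)]:
            result.add(fid, s)
    return result


def select_dex(fmap: FeatureMap, exclusion_span: int = 2, ppm: float = 10.0) -> SelectionResult:
    """DDA with dynamic exclusion of recently fragmented m/z values.

    A signal whose m/z lies within ``ppm`` of any precursor scheduled in the
    previous ``exclusion_span`` fractions is skipped; skipped slots are
    refilled by the next most intense eligible signal in the same spectrum.
    """
    if exclusion_span < 0:
        raise ValueError("exclusion_span must be >= 0")
    by_id = {f.feature_id: f for f in fmap.features}
    result = SelectionResult()
    recent: list[tuple[int, float]] = []  # (fraction, mz) of scheduled precursors
    for s in range(fmap.n_fractions):
        excluded_mz = [mz for frac, mz in recent if s - exclusion_span <= frac < s]
        candidates = [
            (f.intensity(s), f.feature_id)
            for f in fmap.features
            if s in f.intensity_profile
        ]
        taken = 0
        for fid in _by_intensity(candidates):
            if taken >= fmap.capacity(s):
                break
            mz = by_id[fid].mz
            if any(abs(mz - emz) <= emz * ppm * 1e-6 for emz in excluded_mz):
                continue
            result.add(fid, s)
            recent.append((s, mz))
            taken += 1
    return result


def _argmax_fraction(f: Feature) -> tuple[int, float]:
    """Highest-intensity fraction of a feature, earliest on ties."""
    best_s = min(
        f.intensity_profile, key=lambda s: (-f.intensity_profile[s], s)
    )
    return best_s, f.intensity_profile[best_s]


def select_greedy(fmap: FeatureMap) -> SelectionResult:
    """Each feature at its argmax fraction; per fraction keep the cap_s best."""
    assigned: dict[int, list[tuple[float, str]]] = {}
    for f in fmap.features:
        s, intensity = _argmax_fraction(f)
        assigned.setdefault(s, []).append((intensity, f.feature_id))
    result = SelectionResult()
    for s in sorted(assigned):
        for fid in _by_intensity(assigned[s])[: fmap.capacity(s)]:
            result.add(fid, s)
    return result


def sps_ranking(fmap: FeatureMap) -> list[str]:
    """Feature ids sorted by maximal intensity descending (ties by id).

    This is the static inclusion-list order SPS consumes; the feature ILP
    uses the same ranking for tie-breaking so that the two strategies
    coincide when the ILP's protein terms are switched off.
    """
    return _by_intensity([(f.max_intensity, f.feature_id) for f in fmap.features])


def select_sps(fmap: FeatureMap, budget: int | None = None) -> SelectionResult:
    """Static intensity-sorted selection.

    Features are ranked by maximal intensity and scheduled in rank order
    into their best still-available fraction (highest intensity with free
    capacity, earliest on ties).  Only the first ``budget`` schedulable
    entries are returned; ``None`` means no budget limit.
    """
    if budget is not None and budget < 0:
        raise ValueError("budget must be >= 0")
    by_id = {f.feature_id: f for f in fmap.features}
    remaining = {s: fmap.capacity(s) for s in range(fmap.n_fractions)}
    result = SelectionResult()
    for fid in sps_ranking(fmap):
        if budget is not None and len(result.selected) >= budget:
            break
        f = by_id[fid]
        options = sorted(
            f.intensity_profile, key=lambda s: (-f.intensity_profile[s], s)
        )
        for s in options:
            if remaining[s] > 0:
                remaining[s] -= 1
                result.add(fid, s)
                break
    return result
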