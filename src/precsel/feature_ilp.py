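"""Feature-based inclusion list as an integer linear program.

Given a feature map with per-fraction normalized intensities int_{j,s} and
spectrum capacities cap_s, maximize

    sum_{j,s} x_{j,s} * int_{j,s}

subject to per-fraction capacities (sum_j x_{j,s} <= cap_s), a per-feature
selection limit (sum_s x_{j,s} <= max_selections_per_feature, default 1)
and x_{j,s} binary.  Solving the ILP yields a globally optimal inclusion
list: unlike greedy per-feature assignment it can move a feature to a
less intense fraction when that frees capacity for an otherwise lost
feature.

Degeneracy handling: after per-feature normalization every feature's best
fraction has weight exactly 1, so optima are massively tied.  Solutions
are made deterministic by a second lexicographic solve that, among all
optimal solutions, prefers features in static-inclusion-list order
(:func:`precsel.baselines.sps_ranking`) and earlier fractions.  The
reported objective is the proven optimum of the primary problem.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._solver import MilpBuilder, MilpSolution
from .baselines import SelectionResult, sps_ranking
from .data_model import FeatureMap

__all__ = ["FeatureILPModel", "build_feature_ilp", "solve_feature_ilp"]

#: slack on the optimal-value row in the tie-breaking solve
_LEX_TOL = 1e-9


@dataclass
class FeatureILPModel:
    builder: MilpBuilder
    var_index: dict[tuple[str, int], int]
    fmap: FeatureMap
    ranking: list[str]
    budget: int | None = None


def build_feature_ilp(
    fmap: FeatureMap,
    max_selections_per_feature: int = 1,
    budget: int | None = None,
    ranking: list[str] | None = None,
) -> FeatureILPModel:
    """Assemble the feature ILP for a (normalized) feature map.

    ``budget`` adds an optional global row ``sum x_{j,s} <= budget``;
    ``ranking`` overrides the tie-break order (by default the map's own
    intensity-sorted order).
    """
    if not fmap.features:
        raise ValueError("empty feature map")
    if max_selections_per_feature < 1:
        raise ValueError("max_selections_per_feature must be >= 1")
    builder = MilpBuilder()
    var_index: dict[tuple[str, int], int] = {}
    for f in fmap.features:
        for s, intensity in sorted(f.intensity_profile.items()):
            var_index[(f.feature_id, s)] = builder.add_binary(objective=intensity)
    for s in range(fmap.n_fractions):
        row = {v: 1.0 for (fid, frac), v in var_index.items() if frac == s}
        if row:
            builder.add_le(row, fmap.capacity(s))
    for f in fmap.features:
        row = {
            var_index[(f.feature_id, s)]: 1.0 for s in f.intensity_profile
        }
        builder.add_le(row, max_selections_per_feature)
    if budget is not None:
        builder.add_le({v: 1.0 for v in var_index.values()}, budget)
    return FeatureILPModel(
        builder=builder,
        var_index=var_index,
        fmap=fmap,
        ranking=ranking if ranking is not None else sps_ranking(fmap),
        budget=budget,
    )


def _tiebreak_preferences(model: FeatureILPModel) -> dict[int, float]:
    """Integer preference scores: feature rank dominates, then earlier fraction."""
    rank = {fid: r for r, fid in enumerate(model.ranking)}
    n, s_total = len(model.ranking), model.fmap.n_fractions
    return {
        v: float((n - rank[fid]) * (s_total + 1) + (s_total - s))
        for (fid, s), v in model.var_index.items()
    }


def solve_lexicographic(
    builder: MilpBuilder, preferences: dict[int, float]
) -> tuple[float, "MilpSolution"]:
    """Solve, then re-solve for the preferred solution among all optima.

    Returns the proven primary optimum and the tie-broken solution.  The
    second stage pins the primary objective to its optimal value (within a
    tiny slack) and maximizes the integer preference score, which has a
    unique optimum, so the returned solution is deterministic.
    """
    primary = {i: c for i, c in enumerate(builder.objective) if c != 0.0}
    first = builder.solve()
    builder.add_constraint(
        primary, lb=first.objective - _LEX_TOL * max(1.0, abs(first.objective))
    )
    for i in range(builder.n_variables):
        builder.set_objective(i, preferences.get(i, 0.0))
    second = builder.solve()
    return first.objective, second


def solve_feature_ilp(model: FeatureILPModel) -> tuple[SelectionResult, float]:
    """Solve to proven optimality; return the selection and the optimal objective.

    The selection lists each chosen (feature, fraction) pair once, ordered
    by the model's ranking, and respects every capacity and per-feature
    limit row exactly.
    """
    objective, sol = solve_lexicographic(model.builder, _tiebreak_preferences(model))
    rank = {fid: r for r, fid in enumerate(model.ranking)}
    chosen = [
        (fid, s)
        for (fid, s), v in model.var_index.items()
        if sol.value(v) > 0.5
    ]
    chosen.sort(key=lambda t: (rank[t[0]], t[1]))
    result = SelectionResult()
    for fid, s in chosen:
        result.add(fid, s)
    return result, objective
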