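"""Iterative precursor ion selection (IPS_LP).

With LC-MALDI the sample is frozen on the target plate, so MS/MS
acquisition can proceed in rounds: select a batch of precursors, acquire
and search their spectra, then re-optimize in the light of the new peptide
and protein evidence.  Each round solves a combined ILP whose objective
has three parts:

* protein-based inclusion ``k1 * sum_i z_i`` — z_i rises to 1 once protein
  i reaches the probability threshold c, counting both real peptide IDs
  and the "theoretical" evidence of scheduled features matching the
  protein's tryptic peptides;
* feature-based inclusion ``k2 * sum x_{j,s} int_{j,s}`` — the static
  feature ILP objective, keeping the discovery character of DDA;
* exclusion ``-k3 * sum_{i identified} sum matches m_{p,j} x_{j,s}`` —
  features that likely belong to already-identified proteins lose weight.

Feature-peptide matching combines an m/z window (ppm) with an RT matching
probability r_{p,j}: the Gaussian RT-prediction-error mass falling between
t_p - maxRT(j) and t_p - minRT(j).  Detectability and RT match are treated
as independent, m_{p,j} = d_p * r_{p,j}.

A sequential variant walks the fractions in plate order: fractions after
the current one are closed, earlier fractions are frozen at their
historical selection counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from scipy.stats import norm

from ._solver import MilpBuilder
from .baselines import SelectionResult, sps_ranking
from .data_model import (
    FeatureMap,
    PSM,
    PeptideEntry,
    ProteinEntry,
    ValidationError,
    normalize_intensities,
)
from .protein_lp import DEFAULT_PSEUDO, protein_probability

__all__ = [
    "rt_matching_probability",
    "matching_probability",
    "protein_indicator",
    "protein_log_ratio",
    "MatchSet",
    "build_match_sets",
    "IPSParams",
    "IPSState",
    "IPSModel",
    "build_ips_model",
    "IterationRecord",
    "run_ips",
]

SearchOracle = Callable[[str, int], PSM | None]


# ---------------------------------------------------------------------------
# matching probabilities


def rt_matching_probability(
    t_p: float, rt_min: float, rt_max: float, mu: float = 0.0, sigma: float = 30.0
) -> float:
    """Probability the RT prediction error places peptide p inside feature j.

    The prediction error t_p - t_obs is Gaussian(mu, sigma); the feature
    covers observed RTs [rt_min, rt_max], so the error must fall within
    [t_p - rt_max, t_p - rt_min].
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    if rt_min > rt_max:
        raise ValidationError("rt_min must be <= rt_max")
    x1 = t_p - rt_max
    x2 = t_p - rt_min
    return float(norm.cdf((x2 - mu) / sigma) - norm.cdf((x1 - mu) / sigma))


def matching_probability(d_p: float, r_pj: float) -> float:
    """m_{p,j} = d_p * r_{p,j} (detectability and RT match independent)."""
    return d_p * r_pj


def protein_indicator(p_i: float, c: float) -> int:
    """Binary switch b_i: 1 once protein i passed the probability threshold c."""
    if not 0.0 < c < 1.0:
        raise ValidationError("c must be in (0,1)")
    return 1 if p_i >= c else 0


def protein_log_ratio(p_i: float, c: float, delta: float = DEFAULT_PSEUDO) -> float:
    """Continuous ratio log(1-P_i)/log(1-c); >= 1 exactly when P_i >= c."""
    if not 0.0 < c < 1.0:
        raise ValidationError("c must be in (0,1)")
    p = min(p_i, 1.0 - delta)
    return math.log(1.0 - p) / math.log(1.0 - c)


@dataclass(frozen=True)
class MatchSet:
    """Features plausibly produced by one theoretical peptide.

    ``features`` holds (feature_id, m_{p,j}) for every feature whose m/z is
    within ``ppm_window`` of the peptide's theoretical m/z.
    """

    peptide: PeptideEntry
    features: tuple[tuple[str, float], ...]
    ppm_window: float


def build_match_sets(
    proteins: Sequence[ProteinEntry],
    fmap: FeatureMap,
    ppm: float,
    mu: float = 0.0,
    sigma: float = 30.0,
) -> list[MatchSet]:
    """m/z-window match sets with RT/detectability matching probabilities.

    The m/z window only decides membership of M_p; mass accuracy itself
    does not enter m_{p,j}.
    """
    peptides: dict[str, PeptideEntry] = {}
    for prot in proteins:
        for pep in prot.peptides:
            peptides.setdefault(pep.sequence, pep)
    out = []
    for seq in sorted(peptides):
        pep = peptides[seq]
        members = []
        for f in fmap.features:
            if abs(f.mz - pep.mz_theoretical) <= pep.mz_theoretical * ppm * 1e-6:
                r = rt_matching_probability(
                    pep.predicted_rt, f.rt_min, f.rt_max, mu=mu, sigma=sigma
                )
                members.append((f.feature_id, matching_probability(pep.detectability, r)))
        out.append(MatchSet(peptide=pep, features=tuple(members), ppm_window=ppm))
    return out


# ---------------------------------------------------------------------------
# state and model


@dataclass
class IPSParams:
    """Tunable weights and loop controls of the iterative selection."""

    k1: float = 10.0
    k2: float = 1.0
    k3: float = 10.0
    c: float = 0.95
    step_size: int = 10
    ppm: float = 10.0
    rt_mu: float = 0.0
    rt_sigma: float = 30.0
    delta: float = DEFAULT_PSEUDO
    max_iterations: int = 1000
    max_precursors: int | None = None
    efficiency_window: int = 0  # 0 disables the efficiency stop
    efficiency_threshold: float = 0.0
    sequential: bool = False
    #: stop once this many proteins are identified (None = run to exhaustion)
    target_protein_count: int | None = None
    #: resolve once more for a canonical solution among ties; disable to
    #: halve solver time when only identification counts matter
    deterministic_tiebreak: bool = True


@dataclass
class IPSState:
    """Acquisition state threaded through the iterative loop."""

    fragmented: list[tuple[str, int]] = field(default_factory=list)
    psms: list[PSM] = field(default_factory=list)
    peptide_probs: dict[str, float] = field(default_factory=dict)
    protein_probs: dict[str, float] = field(default_factory=dict)
    candidates: dict[str, ProteinEntry] = field(default_factory=dict)
    current_fraction: int = 0  # s* of the sequential mode

    @property
    def precs(self) -> int:
        return len(self.fragmented)

    def identified(self, c: float) -> set[str]:
        return {acc for acc, p in self.protein_probs.items() if p >= c}

    def record_psm(self, psm: PSM, database: Mapping[str, ProteinEntry]) -> None:
        """Fold one PSM into peptide/protein probabilities (max per peptide)."""
        self.psms.append(psm)
        seq = psm.peptide_sequence
        prev = self.peptide_probs.get(seq, 0.0)
        self.peptide_probs[seq] = max(prev, psm.probability)
        for acc, prot in database.items():
            if any(p.sequence == seq for p in prot.peptides):
                self.candidates[acc] = prot
        for acc, prot in self.candidates.items():
            probs = [
                self.peptide_probs[p.sequence]
                for p in prot.peptides
                if p.sequence in self.peptide_probs
            ]
            self.protein_probs[acc] = protein_probability(probs)


@dataclass
class IPSModel:
    builder: MilpBuilder
    x_vars: dict[tuple[str, int], int]
    z_vars: dict[str, int]
    ranking: list[str]
    fmap: FeatureMap


def build_ips_model(
    state: IPSState,
    fmap: FeatureMap,
    matches: Sequence[MatchSet],
    params: IPSParams,
    ranking: list[str] | None = None,
) -> IPSModel:
    """Assemble the combined inclusion/exclusion ILP for one iteration.

    ``fmap`` must carry per-feature normalized intensities.  Variables of
    already fragmented precursors are fixed at 1; the budget row limits the
    total to precs + step_size.  With no candidate proteins the model
    reduces to the feature ILP plus the budget row.
    """
    builder = MilpBuilder()
    x_vars: dict[tuple[str, int], int] = {}
    by_id = {f.feature_id: f for f in fmap.features}
    for f in fmap.features:
        for s, intensity in sorted(f.intensity_profile.items()):
            x_vars[(f.feature_id, s)] = builder.add_binary(
                objective=params.k2 * intensity
            )
    for fid, s in state.fragmented:
        builder.fix(x_vars[(fid, s)], 1.0)

    log_c = math.log(1.0 - params.c)
    # exclusion term: features matching peptides of identified proteins
    identified = state.identified(params.c)
    z_vars: dict[str, int] = {}
    for acc in sorted(state.candidates):
        z_vars[acc] = builder.add_continuous(objective=params.k1, lb=0.0, ub=1.0)
    for acc in sorted(state.candidates):
        prot = state.candidates[acc]
        prot_peptides = {p.sequence for p in prot.peptides}
        ratio = protein_log_ratio(
            state.protein_probs.get(acc, 0.0), params.c, params.delta
        )
        row: dict[int, float] = {z_vars[acc]: 1.0}
        b_i = protein_indicator(state.protein_probs.get(acc, 0.0), params.c)
        for mset in matches:
            if mset.peptide.sequence not in prot_peptides:
                continue  # a_{i,p} = 0
            for fid, m_pj in mset.features:
                if m_pj <= 0.0:
                    continue
                m = min(m_pj, 1.0 - params.delta)
                coef = math.log(1.0 - m) / log_c  # >= 0
                for s in by_id[fid].intensity_profile:
                    v = x_vars[(fid, s)]
                    row[v] = row.get(v, 0.0) - coef
                    if b_i and acc in identified:
                        builder.add_to_objective(v, -params.k3 * m_pj)
        builder.add_le(row, ratio)

    for s in range(fmap.n_fractions):
        cap_row = {v: 1.0 for (fid, frac), v in x_vars.items() if frac == s}
        if cap_row:
            builder.add_le(cap_row, fmap.capacity(s))
    for f in fmap.features:
        builder.add_le(
            {x_vars[(f.feature_id, s)]: 1.0 for s in f.intensity_profile}, 1
        )
    builder.add_le(
        {v: 1.0 for v in x_vars.values()}, state.precs + params.step_size
    )

    if params.sequential:
        _apply_sequential_constraints(builder, x_vars, state, fmap)

    return IPSModel(
        builder=builder,
        x_vars=x_vars,
        z_vars=z_vars,
        ranking=ranking if ranking is not None else sps_ranking(fmap),
        fmap=fmap,
    )


def _apply_sequential_constraints(
    builder: MilpBuilder,
    x_vars: dict[tuple[str, int], int],
    state: IPSState,
    fmap: FeatureMap,
) -> None:
    """Close fractions after s*, freeze fractions before s* at their history."""
    s_star = state.current_fraction
    counts: dict[int, int] = {}
    for _fid, s in state.fragmented:
        counts[s] = counts.get(s, 0) + 1
    for s in range(fmap.n_fractions):
        row = {v: 1.0 for (fid, frac), v in x_vars.items() if frac == s}
        if not row:
            continue
        if s > s_star:
            builder.add_eq(row, 0.0)
        elif s < s_star:
            builder.add_eq(row, counts.get(s, 0))


def solve_ips_model(
    model: IPSModel, deterministic_tiebreak: bool = True
) -> tuple[SelectionResult, float]:
    """Solve to proven optimality, by default with deterministic tie-breaking."""
    from .feature_ilp import solve_lexicographic

    rank = {fid: r for r, fid in enumerate(model.ranking)}
    if deterministic_tiebreak:
        n, s_total = len(model.ranking), model.fmap.n_fractions
        prefs = {
            v: float((n - rank[fid]) * (s_total + 1) + (s_total - s))
            for (fid, s), v in model.x_vars.items()
        }
        objective, sol = solve_lexicographic(model.builder, prefs)
    else:
        sol = model.builder.solve()
        objective = sol.objective
    chosen = [(fid, s) for (fid, s), v in model.x_vars.items() if sol.value(v) > 0.5]
    chosen.sort(key=lambda t: (rank[t[0]], t[1]))
    result = SelectionResult()
    for fid, s in chosen:
        result.add(fid, s)
    return result, objective


# ---------------------------------------------------------------------------
# the iterative loop


@dataclass
class IterationRecord:
    iteration: int
    selections: list[tuple[str, int]]
    psms: list[PSM]
    objective: float
    identified: set[str]
    precs_total: int


def _advance_fraction(state: IPSState, fmap: FeatureMap) -> None:
    """Move s* forward past exhausted fractions (sequential mode)."""
    fragmented_ids = {fid for fid, _ in state.fragmented}
    counts: dict[int, int] = {}
    for _fid, s in state.fragmented:
        counts[s] = counts.get(s, 0) + 1
    while state.current_fraction < fmap.n_fractions:
        s = state.current_fraction
        cap_left = fmap.capacity(s) - counts.get(s, 0)
        eligible = any(
            s in f.intensity_profile and f.feature_id not in fragmented_ids
            for f in fmap.features
        )
        if cap_left > 0 and eligible:
            return
        state.current_fraction += 1


def run_ips(
    fmap: FeatureMap,
    database: Sequence[ProteinEntry],
    search_oracle: SearchOracle,
    params: IPSParams | None = None,
) -> list[IterationRecord]:
    """Run the full iterative acquisition loop.

    ``database`` is the digested protein search space (peptides with
    predicted RT/detectability attached); ``search_oracle`` maps a
    fragmented (feature_id, fraction) to a PSM or None.  Returns the
    per-iteration history.  The loop stops when the budget or iteration
    limits are hit, when no feature contributes positively to the
    objective (no new selections), or when the identification efficiency
    over the last ``efficiency_window`` iterations drops below threshold.
    """
    params = params or IPSParams()
    if not fmap.features:
        return []
    norm_map = normalize_intensities(fmap)
    ranking = sps_ranking(fmap)  # raw-intensity static order, shared with SPS
    db = {p.accession: p for p in database}
    state = IPSState()
    history: list[IterationRecord] = []
    recent_new_proteins: list[int] = []

    for iteration in range(1, params.max_iterations + 1):
        if params.sequential:
            _advance_fraction(state, norm_map)
            if state.current_fraction >= norm_map.n_fractions:
                break
        if (
            params.max_precursors is not None
            and state.precs >= params.max_precursors
        ):
            break
        matches = build_match_sets(
            sorted(state.candidates.values(), key=lambda p: p.accession),
            norm_map,
            ppm=params.ppm,
            mu=params.rt_mu,
            sigma=params.rt_sigma,
        )
        model = build_ips_model(state, norm_map, matches, params, ranking=ranking)
        selection, objective = solve_ips_model(
            model, deterministic_tiebreak=params.deterministic_tiebreak
        )
        already = set(state.fragmented)
        new = [pair for pair in selection.selected if pair not in already]
        if params.max_precursors is not None:
            new = new[: params.max_precursors - state.precs]
        if not new:
            break  # nothing contributes positively any more
        before = state.identified(params.c)
        iteration_psms: list[PSM] = []
        for fid, s in new:
            state.fragmented.append((fid, s))
            psm = search_oracle(fid, s)
            if psm is not None:
                iteration_psms.append(psm)
                state.record_psm(psm, db)
        identified = state.identified(params.c)
        history.append(
            IterationRecord(
                iteration=iteration,
                selections=new,
                psms=iteration_psms,
                objective=objective,
                identified=set(identified),
                precs_total=state.precs,
            )
        )
        recent_new_proteins.append(len(identified) - len(before))
        if (
            params.target_protein_count is not None
            and len(identified) >= params.target_protein_count
        ):
            break
        if params.efficiency_window > 0 and len(recent_new_proteins) >= params.efficiency_window:
            rate = (
                sum(recent_new_proteins[-params.efficiency_window :])
                / params.efficiency_window
            )
            if rate < params.efficiency_threshold:
                break
    return history
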