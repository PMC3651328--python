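"""Synthetic ground truth and acquisition simulation.

The evaluation design mirrors an "extensive fragmentation" experiment: a
single synthetic LC-MS feature map with known peptide/protein annotations
is generated once, and every selection strategy replays its acquisition
against that shared pool.  Spectra themselves are never simulated — only
which precursor is selected and whether its (pre-drawn) identification
succeeds — so differences between strategies cannot be confounded with
technical replication noise.

What the generator emulates:

* random protein sequences with vertebrate-like residue frequencies, so
  tryptic cleavage-site density is realistic;
* log-normal protein abundance;
* peptide observability thresholded by predicted detectability (a feature
  exists with probability d_p);
* Gaussian RT prediction error: observed feature RT = predicted RT +
  N(mu=0, sigma);
* multi-fraction Gaussian elution profiles scaled by protein abundance;
* m/z measurement noise in ppm, plus a configurable fraction of
  unannotated noise features;
* probabilistic identification outcomes: success with a configured rate,
  PSM probability drawn from a Beta distribution whose mean rises with
  the feature's intensity decile, and a small false-identification rate.

Identification outcomes are drawn once per feature at generation time, so
a feature's fate is independent of when (or by which strategy) it is
fragmented — every strategy faces the identical experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import Feature, FeatureMap, PSM, ProteinEntry, ValidationError
from .predictors import LogisticDetectabilityPredictor
from .protein_lp import digest_proteins, protein_probability

__all__ = [
    "SimParams",
    "GroundTruth",
    "MetricsReport",
    "generate_ground_truth",
    "simulate_search",
    "make_search_oracle",
    "acquisition_curve",
    "precursors_to_reach",
    "compute_metrics",
]

# approximate vertebrate proteome residue frequencies (percent)
_RESIDUE_FREQS = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "E": 7.1, "Q": 4.8,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}


@dataclass
class SimParams:
    """Study conditions of the synthetic benchmark."""

    n_proteins: int = 50
    gradient_length: float = 3000.0
    bin_width: float = 30.0
    capacity: int = 25
    protein_length_log_mean: float = math.log(300.0)
    protein_length_log_sigma: float = 0.35
    abundance_log_mean: float = math.log(1e5)
    abundance_log_sigma: float = 1.0
    missed_cleavages: int = 1
    mass_range: tuple[float, float] = (50.0, 4000.0)
    rt_sigma: float = 30.0
    mz_ppm_sigma: float = 2.0
    elution_sigma_fractions: float = 0.7
    elution_cutoff: float = 0.05
    peptide_intensity_log_sigma: float = 0.5
    noise_fraction: float = 0.2
    detectability_override: float | None = None
    id_success_rate: float = 0.9
    false_id_rate: float = 0.01
    psm_beta_concentration: float = 30.0
    psm_mean_low: float = 0.80
    psm_mean_high: float = 0.98


@dataclass
class GroundTruth:
    """Everything the simulator knows that a strategy must discover."""

    proteins: list[ProteinEntry]
    abundances: dict[str, float]
    feature_annotations: dict[str, tuple[str, frozenset[str]] | None]
    id_outcomes: dict[str, tuple[str, float] | None]  # fid -> (peptide, PSM prob)
    observed_rt: dict[str, float]  # fid -> apex RT (annotated features)
    predictor: LogisticDetectabilityPredictor
    params: SimParams

    def peptide_parents(self) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for prot in self.proteins:
            for pep in prot.peptides:
                out[pep.sequence] = pep.parent_accessions
        return out


def _random_protein_sequence(rng: np.random.Generator, length: int) -> str:
    letters = list(_RESIDUE_FREQS)
    probs = np.array([_RESIDUE_FREQS[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def _elution_profile(
    rt: float,
    apex_intensity: float,
    n_fractions: int,
    bin_width: float,
    sigma_fractions: float,
    cutoff: float,
) -> dict[int, float]:
    """Gaussian-shaped intensity over fractions, trimmed at ``cutoff`` of apex."""
    apex = min(max(int(rt / bin_width), 0), n_fractions - 1)
    sigma_rt = max(sigma_fractions * bin_width, 1e-6)
    profile: dict[int, float] = {}
    reach = max(1, int(math.ceil(3 * sigma_fractions)))
    for s in range(max(0, apex - reach), min(n_fractions, apex + reach + 1)):
        center = (s + 0.5) * bin_width
        w = math.exp(-0.5 * ((center - rt) / sigma_rt) ** 2)
        if w >= cutoff:
            profile[s] = apex_intensity * w
    if not profile:
        profile = {apex: apex_intensity}
    # enforce contiguity (cutoff can only trim the tails of a unimodal shape)
    lo, hi = min(profile), max(profile)
    return {s: profile.get(s, apex_intensity * cutoff) for s in range(lo, hi + 1)}


def generate_ground_truth(
    seed: int,
    params: SimParams | None = None,
) -> tuple[FeatureMap, GroundTruth]:
    """Generate a synthetic LC-MS map plus its annotation ground truth.

    Deterministic given ``seed``: repeated calls return identical maps.
    """
    params = params or SimParams()
    if params.bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    rng = np.random.default_rng(seed)
    n_fractions = int(math.ceil(params.gradient_length / params.bin_width))

    raw = []
    for i in range(params.n_proteins):
        length = int(
            np.clip(
                rng.lognormal(params.protein_length_log_mean, params.protein_length_log_sigma),
                80,
                1000,
            )
        )
        raw.append(
            ProteinEntry(
                accession=f"SYN{i:04d}",
                sequence=_random_protein_sequence(rng, length),
            )
        )

    predictor = LogisticDetectabilityPredictor(
        gradient_start=0.0,
        gradient_end=params.gradient_length,
        rt_error_sigma=params.rt_sigma,
    )
    # calibrate the additive RT model on the sample's own peptides
    from .data_model import digest_tryptic

    all_peps = sorted(
        {
            pep
            for prot in raw
            for pep in digest_tryptic(prot.sequence, params.missed_cleavages)
            if len(pep) >= 4
        }
    )
    predictor.calibrate(all_peps)
    proteins = digest_proteins(
        raw,
        predictor,
        missed_cleavages=params.missed_cleavages,
        mass_range=params.mass_range,
    )

    abundances = {
        p.accession: float(rng.lognormal(params.abundance_log_mean, params.abundance_log_sigma))
        for p in proteins
    }

    peptides: dict[str, tuple] = {}
    for prot in proteins:
        for pep in prot.peptides:
            peptides.setdefault(pep.sequence, pep)

    features: list[Feature] = []
    annotations: dict[str, tuple[str, frozenset[str]] | None] = {}
    observed_rt: dict[str, float] = {}
    counter = 0
    for seq in sorted(peptides):
        pep = peptides[seq]
        d = (
            params.detectability_override
            if params.detectability_override is not None
            else pep.detectability
        )
        if rng.random() >= d:
            continue
        rt = pep.predicted_rt + rng.normal(0.0, params.rt_sigma)
        rt = float(np.clip(rt, 0.0, params.gradient_length - 1e-9))
        abundance = max(abundances[acc] for acc in pep.parent_accessions)
        apex = abundance * float(
            rng.lognormal(0.0, params.peptide_intensity_log_sigma)
        )
        profile = _elution_profile(
            rt,
            apex,
            n_fractions,
            params.bin_width,
            params.elution_sigma_fractions,
            params.elution_cutoff,
        )
        lo, hi = min(profile), max(profile)
        mz = pep.mz_theoretical * (1.0 + rng.normal(0.0, params.mz_ppm_sigma) * 1e-6)
        fid = f"F{counter:05d}"
        counter += 1
        features.append(
            Feature(
                feature_id=fid,
                mz=mz,
                charge=pep.charge,
                rt_min=lo * params.bin_width,
                rt_max=(hi + 1) * params.bin_width,
                intensity_profile=profile,
            )
        )
        annotations[fid] = (seq, pep.parent_accessions)
        observed_rt[fid] = rt

    n_noise = int(round(params.noise_fraction * len(features)))
    mz_lo = min((f.mz for f in features), default=500.0)
    mz_hi = max((f.mz for f in features), default=3000.0)
    for _ in range(n_noise):
        rt = float(rng.uniform(0.0, params.gradient_length - 1e-9))
        apex = float(rng.lognormal(params.abundance_log_mean - 1.0, params.abundance_log_sigma))
        profile = _elution_profile(
            rt,
            apex,
            n_fractions,
            params.bin_width,
            params.elution_sigma_fractions,
            params.elution_cutoff,
        )
        lo, hi = min(profile), max(profile)
        fid = f"F{counter:05d}"
        counter += 1
        features.append(
            Feature(
                feature_id=fid,
                mz=float(rng.uniform(mz_lo, mz_hi)),
                charge=1,
                rt_min=lo * params.bin_width,
                rt_max=(hi + 1) * params.bin_width,
                intensity_profile=profile,
            )
        )
        annotations[fid] = None

    fmap = FeatureMap(
        features=tuple(features),
        n_fractions=n_fractions,
        fraction_rt={s: (s + 0.5) * params.bin_width for s in range(n_fractions)},
        capacities={s: params.capacity for s in range(n_fractions)},
    )

    # pre-draw identification outcomes: one fate per feature
    annotated = [f for f in features if annotations[f.feature_id] is not None]
    apex_int = np.array([f.max_intensity for f in annotated])
    deciles = (
        np.searchsorted(np.quantile(apex_int, np.linspace(0.1, 0.9, 9)), apex_int)
        if len(annotated)
        else np.array([])
    )
    all_peptide_seqs = sorted(peptides)
    outcomes: dict[str, tuple[str, float] | None] = {}
    for f, dec in zip(annotated, deciles):
        seq, _parents = annotations[f.feature_id]
        if rng.random() < params.id_success_rate:
            mean = params.psm_mean_low + (params.psm_mean_high - params.psm_mean_low) * dec / 9.0
            k = params.psm_beta_concentration
            prob = float(rng.beta(mean * k, (1.0 - mean) * k))
            outcomes[f.feature_id] = (seq, prob)
        elif rng.random() < params.false_id_rate and len(all_peptide_seqs) > 1:
            wrong = all_peptide_seqs[int(rng.integers(len(all_peptide_seqs)))]
            prob = float(rng.beta(0.6 * 10, 0.4 * 10))
            outcomes[f.feature_id] = (wrong, prob)
        else:
            outcomes[f.feature_id] = None
    for f in features:
        if annotations[f.feature_id] is None:
            if rng.random() < params.false_id_rate and all_peptide_seqs:
                wrong = all_peptide_seqs[int(rng.integers(len(all_peptide_seqs)))]
                outcomes[f.feature_id] = (wrong, float(rng.beta(6, 4)))
            else:
                outcomes[f.feature_id] = None

    truth = GroundTruth(
        proteins=proteins,
        abundances=abundances,
        feature_annotations=annotations,
        id_outcomes=outcomes,
        observed_rt=observed_rt,
        predictor=predictor,
        params=params,
    )
    return fmap, truth


def simulate_search(feature_id: str, fraction: int, truth: GroundTruth) -> PSM | None:
    """Return the pre-drawn identification outcome for a fragmented precursor."""
    outcome = truth.id_outcomes.get(feature_id)
    if outcome is None:
        return None
    seq, prob = outcome
    return PSM(
        precursor_ref=feature_id,
        peptide_sequence=seq,
        probability=prob,
        fraction=fraction,
    )


def make_search_oracle(truth: GroundTruth):
    """Bind the ground truth into a (feature_id, fraction) -> PSM oracle."""

    def oracle(feature_id: str, fraction: int) -> PSM | None:
        return simulate_search(feature_id, fraction, truth)

    return oracle


# ---------------------------------------------------------------------------
# metrics


def acquisition_curve(
    order: Sequence[tuple[str, int]], truth: GroundTruth, c: float = 0.95
) -> list[int]:
    """Identified-protein count after each acquired precursor.

    A protein counts once the aggregated probability of its identified
    peptides (independence aggregation, best PSM per peptide) reaches c.
    """
    parents = truth.peptide_parents()
    peptide_probs: dict[str, float] = {}
    protein_peps: dict[str, set[str]] = {}
    identified: set[str] = set()
    curve: list[int] = []
    for fid, frac in order:
        psm = simulate_search(fid, frac, truth)
        if psm is not None:
            seq = psm.peptide_sequence
            prev = peptide_probs.get(seq, 0.0)
            if psm.probability > prev:
                peptide_probs[seq] = psm.probability
                for acc in parents.get(seq, frozenset()):
                    protein_peps.setdefault(acc, set()).add(seq)
                    if acc not in identified:
                        p = protein_probability(
                            [peptide_probs[s] for s in protein_peps[acc]]
                        )
                        if p >= c:
                            identified.add(acc)
        curve.append(len(identified))
    return curve


def precursors_to_reach(curve: Sequence[int], n_proteins: int) -> int | None:
    """First precursor count at which the curve reaches ``n_proteins``."""
    for k, v in enumerate(curve, start=1):
        if v >= n_proteins:
            return k
    return None


@dataclass
class MetricsReport:
    """Comparison metrics over per-strategy acquisition histories."""

    unique_features_selected: dict[str, int]
    proteins_vs_precursors: dict[str, list[tuple[int, int]]]
    savings_vs_sps: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    decile_coverage: dict[str, dict[str, int]] = field(default_factory=dict)


def compute_metrics(
    histories: Mapping[str, Sequence[tuple[str, int]]],
    truth: GroundTruth,
    c: float = 0.95,
    fmap: FeatureMap | None = None,
) -> MetricsReport:
    """Per-figure metrics: unique features, ID curves, savings vs SPS, deciles.

    ``histories`` maps strategy name to its acquisition order.  Savings at
    protein level n is the percent reduction in precursors relative to SPS
    (positive = fewer precursors needed); it requires an 'sps' history.
    When ``fmap`` is given, protein abundance for the decile split is
    estimated as the mean intensity of the protein's annotated features;
    otherwise the true simulated abundances are used.
    """
    if not histories:
        raise ValidationError("histories must be nonempty")
    curves = {
        name: acquisition_curve(order, truth, c) for name, order in histories.items()
    }
    unique = {
        name: len({fid for fid, _ in order}) for name, order in histories.items()
    }
    pvp = {
        name: [(k + 1, v) for k, v in enumerate(curve)]
        for name, curve in curves.items()
    }
    savings: dict[str, list[tuple[int, float]]] = {}
    if "sps" in curves:
        sps_curve = curves["sps"]
        for name, curve in curves.items():
            rows = []
            top = min(max(curve, default=0), max(sps_curve, default=0))
            for n in range(1, top + 1):
                k_sps = precursors_to_reach(sps_curve, n)
                k_str = precursors_to_reach(curve, n)
                if k_sps and k_str:
                    rows.append((n, 100.0 * (k_sps - k_str) / k_sps))
            savings[name] = rows

    # abundance deciles: protein abundance = mean intensity of its features
    abundance = dict(truth.abundances)
    if fmap is not None:
        per_protein: dict[str, list[float]] = {}
        intensities = {f.feature_id: f.max_intensity for f in fmap.features}
        for fid, ann in truth.feature_annotations.items():
            if ann is None or fid not in intensities:
                continue
            for acc in ann[1]:
                per_protein.setdefault(acc, []).append(intensities[fid])
        for acc, vals in per_protein.items():
            abundance[acc] = float(np.mean(vals))
    decile: dict[str, dict[str, int]] = {}
    ranked = sorted(abundance, key=lambda a: -abundance[a])
    n10 = max(1, len(ranked) // 10)
    top_set, bottom_set = set(ranked[:n10]), set(ranked[-n10:])
    parents = truth.peptide_parents()
    for name, order in histories.items():
        top_hits = bottom_hits = 0
        for fid, frac in order:
            psm = simulate_search(fid, frac, truth)
            if psm is None:
                continue
            accs = parents.get(psm.peptide_sequence, frozenset())
            if accs & top_set:
                top_hits += 1
            if accs & bottom_set:
                bottom_hits += 1
        decile[name] = {"top": top_hits, "bottom": bottom_hits}

    return MetricsReport(
        unique_features_selected=unique,
        proteins_vs_precursors=pvp,
        savings_vs_sps=savings,
        decile_coverage=decile,
    )
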