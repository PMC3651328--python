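"""Core domain types for LC-MALDI precursor ion selection.

An LC-MALDI run fractionates the LC gradient onto a target plate: each
fraction (RT bin) holds one MS spectrum with a limited number of possible
MS/MS acquisitions (its *capacity*).  A *feature* is a detected peptide
signal spanning one or more consecutive fractions with an intensity
profile; selecting a feature in a fraction makes it a *precursor*.

This module holds the shared containers (features, peptides, proteins,
inclusion-list entries, PSMs), the canonical TSV readers/writers, in-silico
tryptic digestion and monoisotopic mass computation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyteomics import fasta as _fasta
from pyteomics import mass as _mass
from pyteomics import parser as _parser

__all__ = [
    "Feature",
    "FeatureMap",
    "PeptideEntry",
    "ProteinEntry",
    "InclusionListEntry",
    "PSM",
    "ValidationError",
    "ParseError",
    "digest_tryptic",
    "monoisotopic_mz",
    "normalize_intensities",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "read_psm_table",
    "write_psm_table",
    "write_inclusion_list",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: cleave C-terminal to K or R, suppressed before proline
TRYPSIN_RULE = r"[KR](?!P)"

PROTON_MASS = 1.00727646688


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class ParseError(ValueError):
    """A file does not conform to the canonical tabular format."""


@dataclass(frozen=True)
class Feature:
    """A detected LC-MS signal: m/z, charge, RT span and per-fraction intensities."""

    feature_id: str
    mz: float
    charge: int = 1
    rt_min: float = 0.0
    rt_max: float = 0.0
    intensity_profile: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intensity_profile:
            raise ValidationError(f"feature {self.feature_id}: empty intensity profile")
        if any(v < 0 for v in self.intensity_profile.values()):
            raise ValidationError(f"feature {self.feature_id}: negative intensity")
        if all(v == 0 for v in self.intensity_profile.values()):
            raise ValidationError(f"feature {self.feature_id}: all-zero intensity profile")
        if self.rt_min > self.rt_max:
            raise ValidationError(f"feature {self.feature_id}: rt_min > rt_max")
        lo, hi = self.fraction_span
        if set(self.intensity_profile) != set(range(lo, hi + 1)):
            raise ValidationError(
                f"feature {self.feature_id}: intensity profile fractions not contiguous"
            )

    @property
    def fraction_span(self) -> tuple[int, int]:
        """Inclusive [first, last] fraction indices covered by the feature."""
        keys = self.intensity_profile.keys()
        return min(keys), max(keys)

    @property
    def max_intensity(self) -> float:
        return max(self.intensity_profile.values())

    def intensity(self, fraction: int) -> float:
        return self.intensity_profile.get(fraction, 0.0)


@dataclass(frozen=True)
class FeatureMap:
    """A grid of LC-MS features over ``n_fractions`` RT bins.

    ``capacities`` maps fraction index to cap_s, the maximal number of MS/MS
    precursors acquirable from that fraction's spectrum.
    """

    features: tuple[Feature, ...]
    n_fractions: int
    fraction_rt: Mapping[int, float] = field(default_factory=dict)
    capacities: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.features:
            lo, hi = f.fraction_span
            if lo < 0 or hi >= self.n_fractions:
                raise ValidationError(
                    f"feature {f.feature_id}: span [{lo},{hi}] outside "
                    f"[0,{self.n_fractions})"
                )
        rts = [self.fraction_rt[s] for s in sorted(self.fraction_rt)]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError("fraction_rt must be strictly increasing")
        if any(c < 0 for c in self.capacities.values()):
            raise ValidationError("capacities must be >= 0")

    def capacity(self, fraction: int) -> int:
        return int(self.capacities.get(fraction, 0))

    def with_capacity(self, cap: int) -> "FeatureMap":
        """Return a copy with uniform capacity ``cap`` in every fraction."""
        return replace(self, capacities={s: cap for s in range(self.n_fractions)})

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class PeptideEntry:
    """A (possibly theoretical) peptide with predicted RT and detectability."""

    sequence: str
    mz_theoretical: float
    predicted_rt: float
    detectability: float
    charge: int = 1
    parent_accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= AMINO_ACIDS:
            raise ValidationError(f"invalid peptide sequence {self.sequence!r}")
        if not 0.0 <= self.detectability <= 1.0:
            raise ValidationError(
                f"peptide {self.sequence}: detectability {self.detectability} not in [0,1]"
            )


@dataclass
class ProteinEntry:
    """A protein with its tryptic peptides and current inference state.

    ``probability`` is P_i, the probability the protein is present given the
    PSMs collected so far; ``detectability`` is D_i, the probability at least
    one scheduled peptide of the protein is identified.
    """

    accession: str
    sequence: str
    peptides: list[PeptideEntry] = field(default_factory=list)
    probability: float = 0.0
    detectability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"protein {self.accession}: P outside [0,1]")


@dataclass(frozen=True)
class InclusionListEntry:
    """One scheduled precursor: m/z plus either a fraction or an RT window."""

    mz: float
    mz_tolerance_ppm: float
    fraction: int | None = None
    rt_start: float | None = None
    rt_end: float | None = None
    priority: float = 0.0
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.fraction is None and self.rt_start is None:
            raise ValidationError("inclusion entry needs a fraction or an RT window")


@dataclass(frozen=True)
class PSM:
    """A peptide-spectrum match with a correctness probability."""

    precursor_ref: str
    peptide_sequence: str
    probability: float
    fraction: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"PSM probability {self.probability} not in [0,1]")


# ---------------------------------------------------------------------------
# digestion and mass


def digest_tryptic(protein_sequence: str, missed_cleavages: int = 1) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Returns all peptides with 0..``missed_cleavages`` internal missed sites,
    ordered by start position then length; duplicate sequences occurring at
    different positions are preserved.
    """
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    seq = protein_sequence.upper()
    if not seq or not set(seq) <= AMINO_ACIDS:
        bad = sorted(set(seq) - AMINO_ACIDS)
        raise ValidationError(f"non-amino-acid characters in sequence: {bad}")
    # dedupe identical (position, peptide) pairs: a peptide ending at the
    # protein C-terminus is otherwise emitted once per missed-cleavage count
    seen: set[tuple[int, str]] = set()
    out: list[str] = []
    for pos, pep in _parser.icleave(seq, TRYPSIN_RULE, missed_cleavages=missed_cleavages):
        if (pos, pep) not in seen:
            seen.add((pos, pep))
            out.append(pep)
    return out


def monoisotopic_mz(
    peptide: str,
    charge: int = 1,
    modifications: Mapping[str, float] | None = None,
) -> float:
    """Monoisotopic m/z of a peptide at the given positive charge.

    ``modifications`` maps residue letters to fixed mass offsets in Da
    (e.g. ``{"C": 57.02146}`` for carbamidomethylation).
    """
    if charge < 1:
        raise ValidationError("charge must be >= 1")
    if not peptide or not set(peptide) <= AMINO_ACIDS:
        raise ValidationError(f"invalid peptide {peptide!r}")
    mz = _mass.fast_mass(peptide, charge=charge)
    if modifications:
        offset = sum(modifications.get(aa, 0.0) for aa in peptide)
        mz += offset / charge
    return mz


def normalize_intensities(fmap: FeatureMap) -> FeatureMap:
    """Scale each feature's profile by its own maximum: int_{j,s} in (0, 1].

    The per-feature normalization prevents a bias towards selecting only
    high-intensity features when the intensities act as objective weights.
    """
    feats = []
    for f in fmap.features:
        m = f.max_intensity
        if m <= 0:
            raise ValidationError(f"feature {f.feature_id}: all-zero profile")
        feats.append(
            replace(f, intensity_profile={s: v / m for s, v in f.intensity_profile.items()})
        )
    return replace(fmap, features=tuple(feats))


# ---------------------------------------------------------------------------
# canonical tabular formats

_FEATURE_HEADER = [
    "feature_id",
    "mz",
    "charge",
    "rt_min",
    "rt_max",
    "fraction_start",
    "fraction_end",
    "intensities",
]


def write_feature_table(
    fmap: FeatureMap, path: str | Path, bin_width: float | None = None
) -> None:
    """Write the canonical tab-separated feature table.

    The header line carries ``n_fractions`` and the RT bin width as
    ``#n_fractions=<n> bin_width=<w>`` so the grid can be reconstructed.
    """
    if bin_width is None:
        rts = [fmap.fraction_rt[s] for s in sorted(fmap.fraction_rt)]
        bin_width = rts[1] - rts[0] if len(rts) > 1 else 30.0
    lines = [f"#n_fractions={fmap.n_fractions}\tbin_width={bin_width:g}"]
    lines.append("\t".join(_FEATURE_HEADER))
    for f in fmap.features:
        lo, hi = f.fraction_span
        ints = ",".join(f"{f.intensity_profile[s]:.10g}" for s in range(lo, hi + 1))
        lines.append(
            "\t".join(
                [
                    f.feature_id,
                    f"{f.mz:.6f}",
                    str(f.charge),
                    f"{f.rt_min:.4f}",
                    f"{f.rt_max:.4f}",
                    str(lo),
                    str(hi),
                    ints,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path) -> FeatureMap:
    """Read the canonical feature table written by :func:`write_feature_table`."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    n_fractions = None
    bin_width = 30.0
    start = 0
    if text[0].startswith("#"):
        m = re.search(r"n_fractions=(\d+)", text[0])
        if m:
            n_fractions = int(m.group(1))
        m = re.search(r"bin_width=([\d.eE+-]+)", text[0])
        if m:
            bin_width = float(m.group(1))
        start = 1
    if start >= len(text) or text[start].split("\t") != _FEATURE_HEADER:
        raise ParseError(f"{path}: line {start + 1}: bad or missing header")
    feats: list[Feature] = []
    for lineno, line in enumerate(text[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(_FEATURE_HEADER):
            raise ParseError(f"{path}: line {lineno}: expected {len(_FEATURE_HEADER)} columns")
        try:
            fid, mz, charge, rt_min, rt_max, lo, hi, ints = cols
            lo_i, hi_i = int(lo), int(hi)
            values = [float(v) for v in ints.split(",")]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        if len(values) != hi_i - lo_i + 1:
            raise ParseError(
                f"{path}: line {lineno}: {len(values)} intensities for span "
                f"[{lo_i},{hi_i}]"
            )
        try:
            feats.append(
                Feature(
                    feature_id=fid,
                    mz=float(mz),
                    charge=int(charge),
                    rt_min=float(rt_min),
                    rt_max=float(rt_max),
                    intensity_profile={lo_i + k: v for k, v in enumerate(values)},
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    if n_fractions is None:
        n_fractions = 1 + max((f.fraction_span[1] for f in feats), default=0)
    fraction_rt = {s: (s + 0.5) * bin_width for s in range(n_fractions)}
    return FeatureMap(
        features=tuple(feats), n_fractions=n_fractions, fraction_rt=fraction_rt
    )


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read protein sequences; accession is the first whitespace token of the header."""
    proteins = []
    with _fasta.read(str(path)) as reader:
        for header, seq in reader:
            accession = header.split()[0]
            proteins.append(ProteinEntry(accession=accession, sequence=str(seq)))
    return proteins


def read_psm_table(path: str | Path) -> list[PSM]:
    """Read a PSM TSV: precursor_ref, peptide, probability, fraction."""
    psms = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "precursor_ref")):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        try:
            psms.append(
                PSM(
                    precursor_ref=cols[0],
                    peptide_sequence=cols[1],
                    probability=float(cols[2]),
                    fraction=int(cols[3]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return psms


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    lines = ["precursor_ref\tpeptide\tprobability\tfraction"]
    for p in psms:
        lines.append(
            f"{p.precursor_ref}\t{p.peptide_sequence}\t{p.probability:.6g}\t{p.fraction}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_inclusion_list(
    entries: Sequence[InclusionListEntry], path: str | Path
) -> None:
    """Write the inclusion-list TSV; rt_end is empty for single-fraction schedules."""
    lines = ["mz\tppm_tol\tfraction_or_rt_start\trt_end\tpriority\tsource_ref"]
    for e in entries:
        if e.fraction is not None:
            sched, rt_end = str(e.fraction), ""
        else:
            sched, rt_end = f"{e.rt_start:.4f}", f"{e.rt_end:.4f}"
        lines.append(
            f"{e.mz:.6f}\t{e.mz_tolerance_ppm:g}\t{sched}\t{rt_end}\t"
            f"{e.priority:.6g}\t{e.source_ref}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
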