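"""Protein-sequence-based inclusion list.

Starting from protein sequences alone (no prior LC-MS run), predict an
LC-MS feature for every tryptic peptide (theoretical m/z, predicted RT,
predicted detectability d_p) and choose the peptide set that best covers
the proteins of interest.

Protein inference uses the independence aggregation of ProteinProphet:
the probability that protein i is present given its identified peptides is

    P_i = 1 - prod_j (1 - p_j)

and, before any MS/MS data exist, the *detectability* of a protein given a
set of scheduled peptide selections is the analogous

    D_i = 1 - prod_p (1 - d_p)^{n_p}

where n_p counts the fractions in which peptide p is scheduled.  With
y_i = -log(1 - D_i), maximizing sum_i y_i is linear in the selection
variables, giving the ILP:

    max sum_i y_i
    s.t.  sum_p x_{p,s} <= cap_s                       (per fraction)
          x_{p,s} <= x_p                               (linking)
          sum_p x_p <= max_list_size
          x_{p,s} = 0 for s outside [t_p - ws, t_p + ws]
          y_i = -sum_{p in protein i} sum_s x_{p,s} log(1 - d_p)

Peptides shared between proteins contribute to every parent's y_i.  The
emitted inclusion list carries an RT window [t_p - ws, t_p + ws] per
peptide, so one entry can cover several fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._solver import MilpBuilder
from .data_model import (
    InclusionListEntry,
    PeptideEntry,
    ProteinEntry,
    ValidationError,
    digest_tryptic,
    monoisotopic_mz,
)
from .predictors import PredictorInterface

__all__ = [
    "protein_probability",
    "protein_detectability",
    "digest_proteins",
    "ProteinLPModel",
    "ProteinLPSolution",
    "build_protein_lp",
    "solve_protein_lp",
    "emit_predicted_inclusion_list",
]

logger = logging.getLogger(__name__)

#: pseudo-count replacing a probability of exactly 1 before taking log(1 - p)
DEFAULT_PSEUDO = 1e-5


def _clip_prob(p: float, delta: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0,1]")
    return min(p, 1.0 - delta)


def protein_probability(
    peptide_probs: Iterable[float], delta: float = DEFAULT_PSEUDO
) -> float:
    """P_i = 1 - prod(1 - p_j): probability at least one peptide ID is correct.

    A peptide probability of exactly 1 is replaced by ``1 - delta`` so the
    log-domain reformulation used by the LPs stays finite.
    """
    prod = 1.0
    for p in peptide_probs:
        prod *= 1.0 - _clip_prob(p, delta)
    return 1.0 - prod


def protein_detectability(
    selected_peptides: Iterable[tuple[float, int]], delta: float = DEFAULT_PSEUDO
) -> float:
    """D_i = 1 - prod (1 - d_p)^{times_selected} over scheduled peptides."""
    prod = 1.0
    for d, times in selected_peptides:
        if times < 0:
            raise ValidationError("times_selected must be >= 0")
        prod *= (1.0 - _clip_prob(d, delta)) ** times
    return 1.0 - prod


def digest_proteins(
    proteins: Sequence[ProteinEntry],
    predictor: PredictorInterface,
    missed_cleavages: int = 1,
    mass_range: tuple[float, float] = (500.0, 4000.0),
    charge: int = 1,
    modifications: dict[str, float] | None = None,
) -> list[ProteinEntry]:
    """Digest each protein and attach predicted peptide properties.

    Peptides outside ``mass_range`` (in Da, at neutral mass) are dropped.
    Shared peptide sequences get the union of parent accessions; every
    parent protein lists the shared entry (the a_{i,p} indicator).
    """
    parents: dict[str, set[str]] = {}
    for prot in proteins:
        for pep in digest_tryptic(prot.sequence, missed_cleavages):
            parents.setdefault(pep, set()).add(prot.accession)
    entries: dict[str, PeptideEntry] = {}
    lo, hi = mass_range
    for seq, accs in parents.items():
        mz = monoisotopic_mz(seq, charge=charge, modifications=modifications)
        neutral_mass = (mz - 1.00727646688) * charge
        if not lo <= neutral_mass <= hi:
            continue
        entries[seq] = PeptideEntry(
            sequence=seq,
            mz_theoretical=mz,
            predicted_rt=predictor.rt_predict(seq),
            detectability=predictor.detectability_predict(seq),
            charge=charge,
            parent_accessions=frozenset(accs),
        )
    out = []
    for prot in proteins:
        peps = sorted(
            {p for p in digest_tryptic(prot.sequence, missed_cleavages) if p in entries}
        )
        out.append(
            ProteinEntry(
                accession=prot.accession,
                sequence=prot.sequence,
                peptides=[entries[p] for p in peps],
                probability=prot.probability,
            )
        )
    return out


@dataclass
class ProteinLPModel:
    builder: MilpBuilder
    peptides: list[PeptideEntry]
    proteins: list[ProteinEntry]
    x_ps: dict[tuple[str, int], int]  # (peptide sequence, fraction) -> var
    x_p: dict[str, int]  # peptide sequence -> var
    y_i: dict[str, int]  # protein accession -> var
    ws: float
    gradient: tuple[float, float]


@dataclass
class ProteinLPSolution:
    objective: float
    selected_peptides: list[PeptideEntry]
    schedule: dict[str, list[int]] = field(default_factory=dict)
    y_values: dict[str, float] = field(default_factory=dict)

    def detectability(self, accession: str) -> float:
        """D_i recovered from the LP's y_i = -log(1 - D_i)."""
        return 1.0 - math.exp(-self.y_values.get(accession, 0.0))


def build_protein_lp(
    proteins: Sequence[ProteinEntry],
    fraction_rt: dict[int, float],
    capacities: dict[int, int],
    ws: float,
    max_list_size: int = 1000,
    delta: float = DEFAULT_PSEUDO,
) -> ProteinLPModel:
    """Assemble the detectability-maximizing ILP over digested proteins.

    ``proteins`` must already carry peptides with predicted RT and
    detectability (see :func:`digest_proteins`).  A peptide whose RT window
    [t_p - ws, t_p + ws] covers no fraction is unschedulable and gets no
    variables (logged as a warning).
    """
    if ws <= 0:
        raise ValidationError("ws must be > 0")
    peptides: dict[str, PeptideEntry] = {}
    for prot in proteins:
        for pep in prot.peptides:
            peptides.setdefault(pep.sequence, pep)
    builder = MilpBuilder()
    x_ps: dict[tuple[str, int], int] = {}
    x_p: dict[str, int] = {}
    fractions = sorted(fraction_rt)
    for seq, pep in sorted(peptides.items()):
        in_window = [
            s for s in fractions if abs(fraction_rt[s] - pep.predicted_rt) <= ws
        ]
        if not in_window:
            logger.warning(
                "peptide %s: predicted RT %.1f s outside the gradient; unschedulable",
                seq,
                pep.predicted_rt,
            )
            continue
        x_p[seq] = builder.add_binary()
        for s in in_window:
            v = builder.add_binary()
            x_ps[(seq, s)] = v
            builder.add_le({v: 1.0, x_p[seq]: -1.0}, 0.0)  # linking
    for s in fractions:
        row = {v: 1.0 for (seq, frac), v in x_ps.items() if frac == s}
        if row:
            builder.add_le(row, capacities.get(s, 0))
    if x_p:
        builder.add_le({v: 1.0 for v in x_p.values()}, max_list_size)
    y_i: dict[str, int] = {}
    for prot in proteins:
        y = builder.add_continuous(objective=1.0, lb=0.0)
        y_i[prot.accession] = y
        row: dict[int, float] = {y: 1.0}
        for pep in prot.peptides:
            w = -math.log(1.0 - _clip_prob(pep.detectability, delta))
            for s in fractions:
                v = x_ps.get((pep.sequence, s))
                if v is not None:
                    row[v] = row.get(v, 0.0) - w
        builder.add_eq(row, 0.0)
    grad_lo = min(fraction_rt.values()) if fraction_rt else 0.0
    grad_hi = max(fraction_rt.values()) if fraction_rt else 0.0
    return ProteinLPModel(
        builder=builder,
        peptides=[peptides[s] for s in sorted(peptides)],
        proteins=list(proteins),
        x_ps=x_ps,
        x_p=x_p,
        y_i=y_i,
        ws=ws,
        gradient=(grad_lo, grad_hi),
    )


def solve_protein_lp(model: ProteinLPModel) -> ProteinLPSolution:
    """Solve to proven optimality and extract the scheduled peptide set."""
    sol = model.builder.solve()
    by_seq = {p.sequence: p for p in model.peptides}
    schedule: dict[str, list[int]] = {}
    for (seq, s), v in model.x_ps.items():
        if sol.value(v) > 0.5:
            schedule.setdefault(seq, []).append(s)
    selected = [by_seq[seq] for seq in sorted(schedule)]
    for v in schedule.values():
        v.sort()
    return ProteinLPSolution(
        objective=sol.objective,
        selected_peptides=selected,
        schedule=schedule,
        y_values={acc: sol.value(v) for acc, v in model.y_i.items()},
    )


def emit_predicted_inclusion_list(
    model: ProteinLPModel,
    solution: ProteinLPSolution,
    ppm: float = 10.0,
) -> list[InclusionListEntry]:
    """One RT-window entry per selected peptide, clipped to the gradient."""
    grad_lo, grad_hi = model.gradient
    entries = []
    for pep in solution.selected_peptides:
        entries.append(
            InclusionListEntry(
                mz=pep.mz_theoretical,
                mz_tolerance_ppm=ppm,
                rt_start=max(pep.predicted_rt - model.ws, grad_lo),
                rt_end=min(pep.predicted_rt + model.ws, grad_hi),
                priority=pep.detectability,
                source_ref=pep.sequence,
            )
        )
    return entries
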