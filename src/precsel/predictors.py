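"""Peptide property predictors: retention time and detectability.

The selection models only require a predictor *contract*: an RT estimate in
seconds, a detectability in [0, 1] and the standard deviation of the RT
prediction error (the error is modeled as Gaussian).  The built-in
predictors are deliberately simple, deterministic models —

* RT: an additive retention-coefficient model (sum of per-residue
  coefficients, via ``pyteomics.achrom``) linearly calibrated onto the LC
  gradient;
* detectability: a logistic function of peptide length, hydropathy (GRAVY)
  and basic-residue count.

Any object satisfying :class:`PredictorInterface` can replace them, e.g. a
wrapper around trained regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from pyteomics import achrom


@runtime_checkable
class PredictorInterface(Protocol):
    """Contract every peptide-property predictor must satisfy."""

    rt_error_sigma: float

    def rt_predict(self, sequence: str) -> float: ...

    def detectability_predict(self, sequence: str) -> float: ...


@dataclass
class AdditiveRTPredictor:
    """Additive retention-coefficient RT model calibrated to a gradient.

    The raw score is the sum of published per-residue retention
    coefficients; an affine map places the scores of a calibration peptide
    set inside ``[gradient_start, gradient_end]`` seconds.

    Parameters
    ----------
    gradient_start, gradient_end
        RT range of the LC gradient in seconds.
    rt_error_sigma
        Standard deviation (seconds) of the Gaussian prediction error
        assumed when matching predictions against observed features.
    """

    gradient_start: float = 0.0
    gradient_end: float = 3000.0
    rt_error_sigma: float = 30.0
    _slope: float = field(default=30.0, repr=False)
    _intercept: float = field(default=0.0, repr=False)

    def raw_score(self, sequence: str) -> float:
        return float(achrom.calculate_RT(sequence, achrom.RCs_guo_ph7_0))

    def calibrate(self, sequences: Iterable[str], margin: float = 0.05) -> None:
        """Fit the affine map so the calibration set spans the gradient.

        ``margin`` leaves headroom at both gradient ends so that peptides
        slightly outside the calibration range still map inside it.
        """
        scores = np.array([self.raw_score(s) for s in sequences], dtype=float)
        span = self.gradient_end - self.gradient_start
        lo, hi = float(scores.min()), float(scores.max())
        if hi <= lo:
            self._slope = 0.0
            self._intercept = self.gradient_start + span / 2
            return
        self._slope = span * (1 - 2 * margin) / (hi - lo)
        self._intercept = self.gradient_start + span * margin - self._slope * lo

    def rt_predict(self, sequence: str) -> float:
        return self._intercept + self._slope * self.raw_score(sequence)

    def detectability_predict(self, sequence: str) -> float:  # pragma: no cover
        raise NotImplementedError("RT-only predictor")


@dataclass
class LogisticDetectabilityPredictor(AdditiveRTPredictor):
    """Combined RT + detectability predictor.

    Detectability d_p is a logistic function of features known to correlate
    with peptide observability in MALDI: length (very short and very long
    peptides ionize or fragment poorly), mean hydropathy, and the count of
    basic residues (K/R/H) which aids protonation.  Outputs lie strictly in
    (0, 1).
    """

    length_opt: float = 12.0
    length_scale: float = 7.0
    w_length: float = -1.2
    w_gravy: float = 0.6
    w_basic: float = 0.8
    bias: float = 0.4

    def detectability_predict(self, sequence: str) -> float:
        n = len(sequence)
        gravy = ProteinAnalysis(sequence).gravy()
        basic = sum(sequence.count(aa) for aa in "KRH")
        z = (
            self.bias
            + self.w_length * ((n - self.length_opt) / self.length_scale) ** 2
            + self.w_gravy * gravy
            + self.w_basic * min(basic, 3)
        )
        return float(1.0 / (1.0 + np.exp(-z)))
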