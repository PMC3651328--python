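# Methods

## Setting and notation

LC-MALDI decouples liquid chromatography from MS/MS: the LC eluate is
deposited on a target plate in discrete RT fractions (bins of width
`bin_width`, default 30 s), and each fraction's spectrum allows at most
`cap_s` MS/MS acquisitions (default 25). A *feature* `j` is a detected
peptide signal with m/z, charge (+1 throughout, the MALDI default), an RT
span and a per-fraction intensity profile. Selecting feature `j` in
fraction `s` is encoded by a binary variable `x_{j,s}`. Fraction indices
are 0-based; RT bins are contiguous and uniform.

## Feature-based inclusion list

Objective `max Σ x_{j,s}·int_{j,s}` with per-fraction capacity rows and a
per-feature selection limit (default 1, exposed as a parameter).
Intensities are normalized per feature by the feature's own maximum, so
every feature's best fraction weighs 1 and the objective effectively
maximizes the number of scheduled features with a preference for each
feature's apex — without biasing against low-abundance features.

**Degeneracy.** Per-feature normalization makes optima massively tied
(any budget-sized set of features at their apex scores the same). Rather
than perturbing coefficients — fragile at solver tolerances — the solver
runs twice: the first solve proves the optimum; the second fixes the
objective to that value (slack 1e-9, relative) and maximizes an integer
preference score that ranks features in static-inclusion-list order
(maximal intensity descending, ties by feature id) and prefers earlier
fractions. The preference optimum is unique, so the returned selection is
deterministic, and the *reported* objective is always the stage-one proven
optimum. The MILP backend is HiGHS via `scipy.optimize.milp` with
`mip_rel_gap = 0`, behind a small builder interface so backends remain
swappable.

## Protein probability and detectability

Protein inference uses independence aggregation: the probability protein
`i` is present given its peptides' identification probabilities `p_j` is
`P_i = 1 − Π_j (1 − p_j)`; probabilities of exactly 1 are replaced by
`1 − δ` (δ = 1e-5, configurable) so the log-domain form stays finite.
Shared peptides contribute fully to every parent protein; no
weight-splitting across parents is applied. Before any MS/MS data exist
the same aggregation over predicted peptide detectabilities `d_p` defines
protein detectability `D_i`, and `y_i = −log(1 − D_i)` makes `Σ_i y_i`
linear in the selection variables.

## Predictors

The LP formulations only require a predictor contract (RT in seconds,
detectability in [0,1], and the RT-error standard deviation σ). The
built-ins are deliberately simple, deterministic models:

* **RT** — an additive retention-coefficient model (`pyteomics.achrom`,
  Guo pH-7 coefficients) mapped affinely onto the gradient; `calibrate()`
  fits the map so a reference peptide set spans the gradient with 5%
  margin. The prediction error is modeled as Gaussian(μ, σ) with defaults
  μ = 0, σ = 30 s (one RT bin).
* **Detectability** — a logistic function of peptide length (quadratic
  penalty away from an optimum of 12 residues), GRAVY hydropathy and the
  number of basic residues. Outputs lie strictly in (0,1).

Both are stand-ins satisfying the same interface a trained regression
model would; any object with `rt_predict`, `detectability_predict` and
`rt_error_sigma` can replace them.

## Protein-sequence-based LP

Variables: `x_{p,s}` (peptide `p` scheduled in fraction `s`), `x_p`
(peptide in the list), `y_i ≥ 0`. Constraints: capacities; linking
`x_{p,s} ≤ x_p`; `Σ x_p ≤ max_list_size` (default 1000); `x_{p,s}`
exists only for fractions whose representative RT lies within
`[t_p − ws, t_p + ws]` (window size `ws`, default 150 s); and the `y_i`
definition row. Both `x_{p,s}` and `x_p` are binary. A peptide whose
window covers no fraction is unschedulable and logged. Because one
peptide may be scheduled in several fractions of its window, each
selection multiplies another `(1 − d_p)` into `1 − D_i` — repeated
acquisition genuinely raises the chance of at least one identification.
The emitted inclusion list carries one RT-window entry per selected
peptide (centroid m/z + ppm tolerance), clipped to the gradient.

## Feature–peptide matching

For each candidate peptide a match set `M_p` contains all features whose
m/z lies within a ppm window (default 10 ppm) of the theoretical m/z; the
window decides membership only. The match probability multiplies
detectability with the RT-match probability
`r_{p,j} = Φ((x2−μ)/σ) − Φ((x1−μ)/σ)` where `x1 = t_p − maxRT(j)`,
`x2 = t_p − minRT(j)`: the Gaussian prediction-error mass that places the
peptide inside the feature's observed RT span.

## Iterative selection (IPS)

Each round solves

```
max k1·Σ_i z_i + k2·Σ x_{j,s}·int_{j,s} − k3·Σ_i b_i·Σ_p Σ_{j∈M_p} Σ_s a_{i,p}·m_{p,j}·x_{j,s}
s.t. z_i ≤ log(1−P_i)/log(1−c) + Σ_p Σ_{j∈M_p} Σ_s x_{j,s}·log(1−a_{i,p}·m_{p,j})/log(1−c)
     z_i ∈ [0,1], capacities, per-feature limit, Σ x_{j,s} ≤ precs + step_size
```

with previously fragmented variables fixed at 1. Defaults k1 = 10,
k2 = 1, k3 = 10; identification threshold c = 0.95. Two distinct
quantities play the role of "protein identified": the *binary* switch
`b_i = [P_i ≥ c]` that turns the exclusion term on, and the *continuous*
log-ratio `log(1−P_i)/log(1−c)` that seeds the `z_i` bound (it exceeds 1
exactly when `P_i ≥ c`, at which point `z_i` saturates at 1 and further
evidence for protein `i` stops paying). Candidate proteins enter the
model as soon as they have one PSM, regardless of significance; per
peptide only the best PSM probability is kept. The model is rebuilt from
scratch each iteration — correctness over warm-start speed.

Termination: iteration/precursor limits, a configurable identification-
efficiency window (new proteins per iteration over the last *w*
iterations below a threshold; off by default since no principled default
window exists), no new selections (nothing contributes positively), and
optionally a target protein count for benchmarking. `z_i` uses the closed
interval [0,1].

**Sequential variant.** The plate is consumed in fraction order: all
fractions after the current one `s*` are closed (`Σ_j x_{j,s} = 0`),
fractions before `s*` are frozen at their historical selection counts,
and `s*` advances when its capacity is exhausted or no unfragmented
feature covers it. Equality-to-capacity for past fractions would be
infeasible when fewer features existed than capacity, so past fractions
are pinned to what was actually selected.

## Synthetic ground truth

The generator emulates an extensive-fragmentation experiment; spectra are
never simulated, only selection outcomes. Defaults (the study
conditions): 50 proteins with vertebrate-like residue frequencies and
log-normal length (median 300 residues); log-normal abundance (σ = 1);
tryptic digestion with 1 missed cleavage and a 50–4000 Da mass window;
observability Bernoulli(d_p) with the logistic predictor as truth; RT =
prediction + Gaussian(0, 30 s); Gaussian elution over fractions
(σ = 0.7 bins, trimmed at 5% of apex) scaled by abundance; 2 ppm m/z
noise; 20% unannotated noise features; identification success rate 0.9
with PSM probabilities Beta-distributed with mean rising from 0.80 to
0.98 across intensity deciles (concentration 30) and a 1% false-ID rate.
Identification fates are pre-drawn per feature at generation time, so
every strategy replays the identical experiment and comparisons are free
of replicate variation.

What the simulator does **not** capture: correlated detectability errors
(the predictor is its own truth, so matching is better calibrated than
with real SVR predictors), chimeric spectra, charge > 1, isotope
interference, and real search-engine score distributions. Passing tests
demonstrate the optimization logic and its claimed reductions, not
instrument-level performance.

## Benchmark sizes and numerical choices

The ten-seed iterative-vs-static benchmark runs the 50-protein default
(~2000 features, 100 fractions) with step_size 50 and stops each run once
the static method's final protein count is reached; the canonical
tie-break re-solve is disabled there because only identification counts
are measured and single-stage HiGHS is already deterministic. Smaller
instances in the unit tests (≤ 10 features × 5 fractions; 3 proteins / 5
peptides / 4 fractions) are sized for exhaustive oracles: brute-force
enumeration and an independent min-cost-flow formulation. Intensity
lattices (multiples of 1/1000) in random test instances make
independently computed objective sums exactly comparable; probability
identities are asserted to 1e-9, normal-CDF values to 1e-4. Degenerate
inputs fail fast: all-zero intensity profiles, zero-width gradients and
out-of-range probabilities raise validation errors at construction.

## Known limitations

* The exclusion term uses raw `m_{p,j}` sums; very large k3 can suppress
  genuinely new features matching identified proteins' m/z windows.
* Protein probabilities ignore peptide-to-protein weight splitting, so
  highly shared peptides can over-count evidence for homologous proteins.
* The additive RT model is crude (no sequence-position effects); σ should
  be re-estimated when swapping in a better predictor.
* The sequential mode cannot revisit skipped fractions, matching plate
  consumption but not the theoretical optimum.
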