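# Methods

## Problem and model

Phenolic compounds built on the 17β-estradiol (E2) backbone inhibit
iron-induced lipid peroxidation (LPO) by donating the phenolic O–H
hydrogen to chain-carrying peroxyl radicals.  Potency is measured as the
molar IC50 for suppressing the TBARS readout in brain homogenate, and
modelled on the −log₁₀(IC50 [M]) scale, where larger is more potent.  The
package implements the descriptor-based QSAR pipeline around eight linear
models of the form

    −log(IC50) = b₀ + Σᵢ bᵢ·xᵢ,   xᵢ ∈ {BDE, SIκ1, SA, logP, HOMO}

together with the machinery to rebuild, validate and apply such models.

## Descriptors

* **BDE (kcal/mol)** — phenolic O–H bond dissociation enthalpy from the
  homolysis cycle BDE = H_r + H_H − H_p, with H_p and H_r the heats of
  formation of the parent phenol and phenoxyl radical and
  H_H = 52.08 kcal/mol the experimental hydrogen-atom value.  H_p and H_r
  come from semi-empirical quantum chemistry and are **inputs**: the
  package deliberately contains no electronic-structure code, and the same
  holds for HOMO (eV).  Lower BDE means an easier H-atom transfer and
  higher predicted potency (negative coefficients).
* **SIκ1 (dimensionless)** — the first-order Kier kappa shape index on
  the hydrogen-suppressed graph, κ1 = A(A−1)²/P₁² with A heavy atoms and
  P₁ heavy-atom bonds.  The *plain* (non-alpha-modified) variant is used:
  it is the canonical first-order index and directly tracks ring count
  (each ring closure raises P₁ at fixed A and lowers κ1; an acyclic chain
  gives exactly A).  Single-atom or disconnected graphs are rejected
  rather than guessed at.
* **SA (Å²)** — solvent-accessible surface area by the Shrake–Rupley
  method: every atom's Bondi van der Waals sphere is inflated by the
  probe radius (default 1.4 Å, water) and covered with a deterministic
  golden-angle spiral lattice (default 960 points/atom; no RNG, so values
  are bit-reproducible); the accessible fraction of lattice points times
  the sphere area is summed over atoms.  Convergence is ~1% against the
  closed-form two-sphere value at ≥2000 points.  Geometry is
  caller-supplied; `MolecularGraph.from_smiles(..., embed3d=True)`
  provides a seeded ETKDG conformer with MMFF minimisation as a
  convenience, and the hydrogen mode (explicit H spheres vs heavy atoms
  only) follows the supplied geometry.  Bondi radii are overridable per
  call.
* **logP (dimensionless)** — Wildman–Crippen atom-contribution estimate
  (sum of published per-atom values over the hydrogen-complete molecule),
  via RDKit's implementation of that table; the table version is recorded
  in output metadata.  The original study used a proprietary estimator,
  so numeric identity is not expected — rank consistency across compounds
  is the design goal.  Elements outside the parameterised set fall back to
  the scheme's wildcard contribution with a warning.

`build_descriptor_table` assembles the matrix, computing SIκ1/SA/logP
from structure where absent, taking BDE from supplied enthalpy pairs and
HOMO from a provider mapping, and records per-value provenance
(`supplied` / `computed` / `missing`); a compound with neither structure
nor values produces an error row, not an exception.

## Model fitting and selection

`fit_ols` solves the least-squares problem directly (numpy), returning
coefficient standard errors, the multiple correlation r, and the ANOVA
decomposition with F = (SSR/k)/(SSE/(n−k−1)) and its upper-tail p from
the F(k, n−k−1) distribution.  Rank-deficient designs raise a
collinearity error naming the dependent columns.

`stepwise_select` is **forward** selection: at each step the candidate
whose addition maximises the overall model F is added, and the enlarged
model is retained only while overall F ≥ 15 — threshold semantics applied
to the whole-model F, matching how the published equations were screened.
Ties are broken lexicographically by descriptor name, making the
procedure a pure function of the table.  Forward direction was chosen
because the published models nest (logP → +BDE/+HOMO → both); no partial-F
entry/removal tests are used, and no multiple-testing correction is
applied (the source reports raw ANOVA p).  Note that once a strong
predictor is in, the *overall* F of a two-term model can stay above
threshold even when the second term is noise; the returned per-size list
makes this visible rather than hiding it.

## Validation

* **Leave-group-out**: refit after removing round(fraction·n) randomly
  chosen compounds (round-half-to-even; 10% of 70 leaves 63), reporting
  coefficient deltas and both r values; fully seeded.
* **y-randomization**: refit after permuting the response (≥100
  permutations), returning the null (r, F) sample and the real model's
  quantile in it.  For single-predictor models the null r carries the
  fitted slope's sign so the null is symmetric about 0 (multiple r is
  non-negative by construction and would fold it).
* **External classification**: a candidate is called more/less potent
  than the reference compound by comparing the *model's* predictions for
  both (predicted-vs-predicted; the experimental reference IC50 is not
  used).  False positive = observed less potent, predicted more potent;
  false negative = the converse.  Exact prediction ties (within
  tie_tol = 1e−9) are counted as incorrect and reported separately.
  `pool_reports` sums counts across models (after excluding named
  models) and keeps exact rationals, rounding to integers only for
  display.

## Dose–response

Percent inhibition is (1 − A/A0)·100; A/A0 is treated as a generic
signal ratio (the assay read fluorescence).  IC50 is estimated by
nonlinear least squares of the logistic model

    y(C) = 100 / (1 + 10^{h·(log₁₀ IC50 − log₁₀ C)})

with floor and ceiling fixed at 0/100 and the Hill slope h free
(initialised at 1; log₁₀ IC50 initialised at the tested concentration
nearest 50% observed inhibition).  All replicate points enter the fit
without pre-averaging.  A fit is flagged non-converged when the optimiser
fails or the estimate leaves the tested range extended 100× on each side
(the inflection was not bracketed).  The free Hill slope is a choice: the
original software's default sigmoid family does not pin h to 1.

## Synthetic data

The generators emulate the study's layout at desk scale: a 70-compound
training table, a 28-compound externally labelled set, and triplicate
5–6-level dose–response curves.  Descriptors are sampled independently
and uniformly over ranges plausible for steroidal phenols
(logP ∈ [1,6], BDE ∈ [72,92] kcal/mol, HOMO ∈ [−9.5,−8.0] eV,
SIκ1 ∈ [8,20], SA ∈ [300,600] Å²); the response is the generating model's
prediction plus N(0, 0.4) on the −log scale.  These are artifact
defaults, not measured values.  Two features of real data are *not*
emulated: descriptors of real steroids are mutually correlated (SA with
SIκ1, logP with SA), and real responses are not homoscedastic Gaussian —
so passing recovery tests demonstrate correctness of the estimators under
the stated model, not performance on laboratory data.  Under these
defaults a single-descriptor fit shows r ≈ 0.7, somewhat above the
0.46–0.57 range seen with the original measurements, whose noise
structure is harsher.  External labels are noiseless model
classifications against a mid-range reference vector, optionally flipped
with a set probability.  Every generator is a pure function of (config,
seed).

## Problem sizes and numerics

Simulation-based tests use the study-scale sizes (n = 70 tables, 28
external compounds, 18-point dose–response designs) with 50–200 seeded
replicates, which keeps the whole suite in tens of seconds.  OLS matches
a normal-equations oracle to 1e−8; SASA point-sampling tolerance is 1%
against the analytic two-sphere value; exact-arithmetic paths (model
fixtures, BDE cycle, pooled rates) are asserted to printed precision.
IC50 units are molar end to end; µM inputs must be converted by the
caller (1 µM = 1e−6 M).

## Interfaces

The numbered scripts under `analysis/` are the pipeline's user
interface (descriptors → simulation → stepwise fit → validation → IC50),
each a thin driver over the library; no separate console command is
installed.  Models serialise losslessly to JSON; tables read and write
plain CSV.

## Known limitations

* No quantum chemistry: BDE inputs and HOMO must come from elsewhere;
  the package cannot rank compounds by BDE from structure alone.
* The Crippen logP will not numerically match values from other
  estimators; only orderings should be compared across software.
* SASA depends on the supplied conformer; the seeded ETKDG embedding is
  a convenience, not a solvated geometry optimisation.
* Forward stepwise under an overall-F threshold can carry noise terms in
  larger models (see above); inspect the per-size list.
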