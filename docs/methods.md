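# Methods

## The model

`mapkfit` models the growth-factor-driven MAP kinase cascade
(Ras-GTP → Raf → MEK → ERK) as a deterministic mass-action reaction
network split into a cytosolic and a nuclear subsystem.

**Topology.** Ras-GTP activates Raf in a single step through a transient
Ras:Raf encounter complex. Raf\* activates MEK *processively*: one
binding event adds both phosphates, with the singly-phosphorylated
intermediate staying enzyme-bound (Raf\*:MEK → Raf\*:MEKp → Raf\* +
MEKpp). MEKpp activates ERK *distributively*: each phosphate requires a
separate binding event and free ERKp is released in between. Each tier
has its own phosphatase (Raf-P'ase, MEK-P'ase, ERK-P'ase); MEK
dephosphorylation mirrors the processive scheme, ERK dephosphorylation
the distributive one. Free MEK, MEKpp, ERK, ERKp and ERKpp shuttle
between cytosol and nucleus with first-order rate constants
κ_in/κ_out; phosphatases do not shuttle. In the nucleus, N-MEKpp
activates ERK distributively and the nuclear MEK/ERK phosphatases
deactivate their substrates, all with rate constants independent of
their cytosolic counterparts (kinetics may differ by location).

This gives exactly 33 species (10 cytosolic free forms, 10 cytosolic
complexes, 7 nuclear free forms, 6 nuclear complexes) and 52 elementary
reactions, each with its own rate constant: binding constants *a* (per
concentration per minute), dissociation *d* and catalytic *k* constants
(per minute), and 10 shuttling constants. The rate-constant count is
always derived from the assembled network object, never assumed
elsewhere in the package.

**Ras input.** Ras-GTP activity is a clamped external driver r(t), not a
state variable: reactions consuming Ras multiply their propensity by
r(t) and the Ras pool is never depleted. The default parametric pulse

    r(t) = A · (t/t_p) · exp(1 − t/t_p)

is zero at stimulation, peaks at amplitude A at t_p = 2 min and decays
slowly, the shape reported by live-cell FRET reporters of
receptor-proximal Ras activation. A tabulated curve can be supplied
instead. Defaults: A = 1.0 for the normalized system, A = 0.4 for the
absolute system.

**Two model variants.**

* *System 1* — every kinase and phosphatase total set to 1 (arbitrary
  units); used when only normalized (ratio) data are available.
* *System 2* — absolute concentrations: Raf 0.013, Raf-P'ase 0.002,
  MEK 1.4, MEK-P'ase 0.14, ERK 0.96, ERK-P'ase 0.48, Ras amplitude 0.4,
  with maximal activated fractions at the 5-min reference of 100% (Raf),
  5% (MEK) and 50% (ERK), giving activated concentrations 0.013, 0.07
  and 0.48 used to rescale normalized traces to absolute ones.

All inactive protein starts in the cytosol and every other species at
zero, with one deliberate exception: the table lists a single
concentration per phosphatase, but the nuclear phosphatases are
independent conserved pools (they do not shuttle), so each compartment's
phosphatase pool is initialized at the tabulated concentration. Setting
the nuclear pools to zero instead would permanently silence the nuclear
deactivation arm. Compartment volumes are treated as equal; any volume
ratio is absorbed into the shuttling constants.

## Numerics

The stiff ODE system is integrated with LSODA (rtol 1e-8, atol 1e-10),
with the right-hand side JIT-compiled; `evaluate_derivatives` is the
plain reference implementation and the two agree to integrator accuracy
(tested). Negative excursions within 1e3·atol of zero are integration
noise and are clamped to zero; anything larger raises an integration
failure. Conserved protein totals drift by less than 1e-7 relative over
20 min even for random rate constants up to 1000 (tested). Output grids
must contain the 5-minute reference point; normalization uses exact grid
membership, and a reference activity below 1e-8 raises a
degenerate-normalization error rather than producing a huge ratio.

Activity observables sum *all* species carrying the fully activated
kinase (free plus complex-bound), since a phospho-specific measurement
does not distinguish bound from free; a `free_only` switch restricts to
free forms.

## Inference

The data are five-point time courses (0, 1, 5, 10, 20 min) of Raf
activity (cytosol only) and MEK/ERK activities (cytosol and nucleus),
each normalized to its own 5-min value. Measured points are linearly
interpolated onto the 1-minute grid over [0, 20] (16 additional points
per trace) and the model is scored by

    E = Σ_i Σ_j ((x_ij − y_ij) / w_i)²

with x simulated, y measured/interpolated, and trace weights w_i = 1 for
normalized traces and the maximal measured activity for absolute traces
(dividing by the weight balances traces of very different amplitudes;
multiplying would do the opposite). The error is summed over the full
21-point grid — this is what makes the interpolation meaningful — with
the consequence discussed under *Limitations*.

The optimizer is a classical binary genetic algorithm over
[0, W_max]^52, W_max = 1000: 16-bit Gray-coded chromosomes per
parameter, linear-ranking fitness (selective pressure 2),
stochastic-universal-sampling selection, single-point crossover
(rate 0.7), bit-flip mutation (rate 1/chromosome length), and
fitness-based reinsertion with generation gap 0.9 (offspring replace the
worst 90%, implicitly preserving the elite). Rate vectors that crash the
integrator or produce degenerate normalizations receive a penalty of
1e12 plus the number of affected traces, keeping the ranking total. The
full profile is 500 generations × 100 individuals with 20 independent
restarts keeping the 10 lowest-error candidates; the desk-scale profile
used throughout the tests and analysis scripts is 100 × 40 with 3–6
restarts. All runs are deterministic given their seed.

What inference can and cannot recover: the model is strongly sloppy —
many rate vectors realize the same five observable traces — so the
package's recovery claim is about *trajectories*, not parameters. The
tested property is that the fitted error reaches the error the
generating rates themselves score on the same (interpolated, possibly
noisy) data.

## Robustness-based selection

For each low-error candidate, rate constants are perturbed
multiplicatively and independently:

    uniform:  k' = k (1 + σ (2U − 1)),   U ~ U(0,1)
    gaussian: k' = max(k (1 + σ Z), 0),  Z ~ N(0,1)

σ is a dimensionless strength (defaults 0.2 uniform, 0.1 gaussian; the
uniform form is centered so σ = 0 is the identity and perturbations are
two-sided). Each perturbed model is simulated and seven kinase
activities (cytosolic Raf; MEK and ERK per compartment and total) are
collected at 20 min. Two summaries are kept: the **average behavior**
A = Σ μ_i (sum of ensemble means, compared against the unperturbed
activities) and the **nominal behavior** V = Σ v_i (sum of ensemble
population variances of the activities). The final estimate is the
candidate with the smallest V; ties break on |A − Σx| and then on fit
error. The same random draws are used for every candidate (shared-draw
design) so the comparison is paired. The reference ensemble size is
10,000; tests and scripts use 1,000, which changes V estimates by a few
percent (V is a sum of variances with ~n⁻¹ᐟ² sampling error).
Variance columns that are bitwise constant are set to exactly zero so
the σ = 0 identity V = 0 holds without mean-rounding noise. Individual
integration failures are dropped and counted; more than 50% failures
aborts the ensemble. Fit error and robustness need not be correlated;
the analysis script logs the pairing but nothing asserts it.

## Phosphatase scenarios

Predictions use the absolute-concentration system. PP2A at relative
abundance s scales the MEK-phosphatase pools in both compartments by s
and, because PP2A also promotes Raf activation upstream (an effect
modeled phenomenologically, not mechanistically via scaffold proteins),
couples the Ras-Raf binding constant linearly: a1 = a1_basal · s. The
linear form is the simplest coupling that recovers the basal constant at
s = 1; the coupling function is injectable if a saturating form is
preferred. MKP3 at abundance s scales the ERK-phosphatase pools
(including the nuclear pool — MKP3 localization is not restricted here)
by s and the MEK-phosphatase pools by 0.75 + 0.25·s, since only about a
quarter of the MEK-directed phosphatase pool tracks MKP3 abundance. At
s = 1 both manipulations reproduce the baseline trajectories bitwise
(tested). The dose-response grid crosses scales 0.3–2 with Ras
amplitudes 0.004–0.4 and reads activated Raf, total MEK and total ERK at
5, 10 and 20 min; integration failures are recorded per cell (NaN) and
never abort the sweep.

## Synthetic data

The generator emulates the structure of SILAC phosphoproteomic ratio
data: five time points; Raf observed in the cytosol only; MEK and ERK in
both compartments; no Ras trace at all (the upstream input is missing
from such datasets, which is why a parametric stand-in drives the
model); each trace normalized to its own 5-min value. Noise is
multiplicative log-normal, y·exp(N(0, s)) with s = √ln(1+cv²) so the
coefficient of variation is exactly cv (default 0.1 — the real dataset's
noise magnitude is unpublished, so cv is a knob, not a claim).
Normalization is applied **after** noising, as ratios are formed from
noisy intensities: the stored 5-min value is exactly 1 and interior
points inherit the reference point's error, inflating their effective CV
by about √2 (tested).

Ground-truth rate vectors are sampled log-uniformly in [10, 1000] — the
upper end of the GA search range, and fast enough that the small
absolute Raf pool (0.013) can push ERK activation past 10% of its total
by 5 min — and resampled (up to 100 tries) until that viability
predicate holds on the absolute-concentration system.

What passing tests on synthetic data do **not** show: the generator has
no peptide-level structure, no missing values, no systematic biases
between compartments, and its noise model is a guess; agreement on
synthetic data demonstrates the machinery (identifiable trajectories,
correct arithmetic, reproducibility), not biological validity of any
fitted rate set.

## Limitations

* **Interpolation floor.** Because E is summed over the dense grid built
  by linear interpolation, a smooth trajectory cannot score zero even on
  noiseless data: the generating rates themselves score E ≈ 1 against
  their own interpolated five-point traces, and perturbed rate vectors
  sometimes score *better* than the truth. Fit quality should therefore
  always be read relative to the true-rates (or noise) floor, never as
  an absolute number.
* The reconstructed network carries 52 rate constants; no attempt is
  made to force any other count, and all outputs record the network's
  own count.
* Scaffold/KSR regulation, 14-3-3 binding, feedback loops, cross-talk
  and stochastic kinetics are out of scope; both compartments have unit
  volume.
* Problem sizes in tests and scripts (GA 100×40 with 3–6 restarts,
  ensembles of 1,000) are desk-scale choices; the full-scale profile
  (500×100, 20 restarts, 10,000 perturbations) is available through the
  same configuration objects.
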