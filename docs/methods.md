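# Methods

`tmstensor` re-implements, as a tested pipeline over synthetic data, a
data-driven analysis of TMS-induced EEG oscillations: single-trial
time-frequency tensorisation, non-negative PARAFAC (canonical polyadic,
CP) decomposition of a 5-way space × frequency × time × subject ×
condition tensor, rank selection by explained variance and the
core-consistency diagnostic (CORCONDIA), and permutation inference on
the condition-mode loadings with the spatial/spectral/temporal factors
held fixed. This note records the model, the numerical choices, and
what the synthetic experiments do and do not establish.

## The model

A 5-way tensor W of baseline-corrected, z-scored induced power is
approximated by a sum of R rank-one terms,

    W[i,j,k,s,c] ≈ Σ_r  a_r[i] · b_r[j] · c_r[k] · d_r[s] · e_r[c],

with every factor entry constrained non-negative for interpretability:
each component is a topography (a_r), a spectrum (b_r), a time course
(c_r), a per-subject strength (d_r) and a per-condition strength (e_r).
The **canonical normalisation** used throughout resolves the CP scale
indeterminacy by giving every mode except the last unit-norm columns;
all component scale lives on the condition mode, so condition loadings
are comparable across models and permutations. Drug effects are read
off that mode as d_r = e_r[post] − e_r[pre].

## Time-frequency chain

Epochs (trials × channels × samples, 1 kHz, −1..+1 s around the pulse)
pass through a fixed order enforced by `tfr.induced_tfr`:

1. **Evoked subtraction** — the per-channel trial average is removed
   from each trial so only non-phase-locked (induced) power remains.
2. **Hann-taper sliding FFT** — frequency-dependent window of 3.5
   cycles (odd sample count, centred), 10 ms steps, 1 Hz bins from 4 to
   45 Hz. The taper is amplitude-normalised (2/Σh) so a unit sinusoid
   maps to unit power whatever the window length; without this, longer
   low-frequency windows get more gain and bias the spectral profile
   downward. Bins whose window leaves the epoch are **flagged undefined
   (NaN)**, never zero-padded — zero-padding would bias the z-transform.
3. **z-transform** — per trial, channel and frequency over the defined
   time bins (SD with n−1); a power value then reads as "SDs away from
   this row's own level".
4. **Baseline correction** — the mean over −100..−50 ms is subtracted
   per row, so values are change from the pre-stimulus baseline.
5. **Average and crop** — trials averaged; axes restricted to 4–34 Hz
   and 40 ms onward. On a −1000..1000 ms grid the default crop gives 31
   frequency × 97 time bins; the container records the actual lengths.

Because a 3.5-cycle window centred near the epoch edge always extends
past it, the cropped block can contain undefined bins; the policy is
explicit (`error` by default, `trim` to drop such time columns, `keep`
to pass NaNs through), and analyses here choose crops that lie wholly
in the defined region.

Two properties of this chain matter for interpretation. First, the
z-transform removes the absolute spectral profile — every
frequency row is rescaled to its own variability — so spectral structure
in the output reflects *temporal modulation relative to the row's noise
floor*, not raw power. Second, with very low broadband noise the
z-transform amplifies window side-lobe leakage from strong bursts into
quiet rows; at realistic noise the leakage sits below each row's noise
floor and the carrier frequency dominates (asserted by test).

## Non-negative CP solver

Alternating least squares in which each mode's subproblem is solved
*exactly*: the objective restricted to one factor matrix decouples over
its rows into R-dimensional non-negative quadratic programs sharing the
Gram matrix H = ∘_{m≠n} F_mᵀF_m, solved by enumerating active sets
(2^R − 1 supports; exact KKT point for positive-definite H), vectorised
across rows. Exact per-mode minimisation makes the objective
non-increasing every sweep — a standing test, and the reason
multiplicative-update NMF-style rules were not used. The data enter
each update only through one MTTKRP (matricised tensor times Khatri-Rao
product) pass, so a full sweep is O(R · #entries).

Numerical choices:

* **Convergence** — relative objective change below `tol` (default
  1e−8) against ‖W‖², or 500 sweeps; exposed in `DecomposeConfig`.
* **Initialisation** — random |N(0,1)| columns, unit-normalised, then
  scaled so the initial model norm matches ‖W‖ (a grossly over-scaled
  start can zero whole columns in the first exact NNLS update). Best of
  4 restarts by residual, seeded and reproducible.
* **Collapse rescue** — a component whose column hits exact zero in two
  or more modes can never re-enter the active set. On structured EEG-like
  data with sparse spectral profiles a noticeable fraction of random
  starts end in such collapsed local minima (all-zero component,
  markedly worse fit). If every restart collapses, up to three extra
  restarts run, then one SVD-based start (absolute leading singular
  vectors of each unfolding, `init="hosvd"`), which in practice lands
  in the structured basin directly. `init="hosvd"` can also be selected
  outright; the random default keeps restart diversity.
* **Exact fits** — explained variance, 100·(1 − ‖W−Ŵ‖²/‖W‖²), is
  computed from factor Grams and one MTTKRP (never a dense
  reconstruction), with the residual clamped at zero so cancellation
  cannot push the fit above 100.

`fixed_modes` freezes chosen factor matrices (returned bit-identical) —
the contract the permutation test relies on.

## CORCONDIA

The core-consistency diagnostic fits the least-squares Tucker core G
given the model's factors and scores 100·(1 − Σ(G−T)²/R) against the
ideal superdiagonal core T. G is computed on the factor-projected
(compressed) tensor — a per-mode pseudoinverse contraction — which
equals the dense least-squares core whenever the factors have full
column rank (equivalence asserted against the explicit Kronecker-system
solution); factors numerically rank-deficient raise instead of
returning an unidentified core.

Two caveats, both visible in the synthetic experiments and both known
properties of the diagnostic rather than implementation artifacts:

* CORCONDIA's noise sensitivity grows with factor collinearity and
  tensor order. Non-negative factors are inherently correlated, and the
  subject/condition loadings of this design are nearly constant columns;
  the pseudoinverse projection then amplifies noise quadratically, so on
  a noisy 5-way tensor the diagnostic can collapse even at the true rank
  while the fit is excellent. The rank-sweep driver reproduces exactly
  this: explained variance plateaus at the generating rank while
  CORCONDIA collapses above rank 2 — the qualitative behaviour the
  original study reported for its recordings.
* On *noiseless* full-column-rank constructions it is exact (100 at the
  true rank, catastrophic collapse when overfactored), which is what the
  acceptance suite asserts.

A related identifiability point: if all condition-loading rows are
identical up to a shared post-drug effect, the condition factor matrix
has column rank ≤ 2, and the rank-3 core is not identified. The
generator therefore exposes `condition_jitter` (per-condition
multiplicative |N(1, j²)| spread, default 0) for experiments that need
full-column-rank condition loadings.

## Permutation inference

The master rank-3 model is fitted once per condition set and put in
canonical form. Each permutation reassigns the S×C grid of 3D
subject/condition slabs, then re-estimates only the subject and
condition loadings by warm-started alternating exact NNLS with the
space/frequency/time factors frozen at their master values. The
contrast recomputed on each refit forms the null; the decision uses the
2.5%/97.5% empirical quantiles and the two-tailed p-value the add-one
convention p = (1 + #{|null| ≥ |d|})/(n_perm + 1), so p ≥ 1/(n_perm+1).
Quantiles are order statistics (`method="higher"`), which keeps the
two-tailed rejection probability at 2·⌊0.025(n_perm+1)⌋/(n_perm+1) ≤ 5%
exactly under exchangeability — ties break toward non-rejection.

**The G-projection shortcut.** The refit depends on the tensor only
through G[s,c,r] = Σ_ijk W[i,j,k,s,c]·a_r[i]·b_r[j]·c_r[k] and the
Hadamard product Φ of the frozen modes' Grams. Slab permutation
commutes with the projection, so G is computed once per dataset (one
pass over the tensor) and each of the 1000 iterations only permutes
G's rows and alternates two tiny NNLS solves — O(S·C·R) per iteration.
Equivalence with the naive full-tensor refit (same update order, same
stopping rule on the full objective) holds to ~1e−15 relative and is a
standing test.

**Two shuffle schemes, deliberately.** `joint` permutes all S·C slabs —
the literal study procedure. `within_subject` permutes conditions
separately inside each subject. When subjects genuinely differ in
component strength, the joint shuffle mixes between-subject variability
into the null while the observed paired contrast is insensitive to it;
the test then becomes severely conservative (empirical type-I error ≈ 0
under the null generator at subject spread 0.2). Under the within-subject
scheme the slabs exchanged are identically distributed under the null
generator, the test is exact, and the measured type-I error is nominal.
The calibration and power suites therefore use `within_subject`;
`joint` remains the default of `permutation_test` for procedure
fidelity, and the headline drivers let the user choose. The model-2
between-drug comparison uses the difference-of-differences
(post−pre)_LEV − (post−pre)_LTG with the same null machinery.

## Synthetic data

The generator emulates the study's structure at configurable scale.
Defaults mirror the recorded dataset: 61 channels, 31 frequency bins
(4–34 Hz), 98 time bins (40–1010 ms in 10 ms steps — the printed
post-crop grid), 13 subjects, 4 conditions, rank 3.

* **Components** — spatial profiles are Gaussian bumps over the packaged
  schematic 10-10 montage centred on Fz (frontal beta, 15–30 Hz), Oz
  (occipital alpha, 6–13 Hz) and C3, the stimulated site (theta,
  4–6 Hz); temporal profiles encode the beta peak → suppression →
  rebound sequence, the delayed alpha rise from ~140 ms to a plateau,
  and the early theta peak (~90–240 ms) with late suppression. Ranks
  above 3 add random smooth non-negative profiles, flagged in metadata.
* **Subject loadings** — |N(1, 0.2²)| by default: inter-subject
  variability is reported by the study but no distribution is given, so
  a 20% spread around a common strength is taken as realistic.
* **Condition loadings and drug effect** — identical rows scaled per
  component (1.2, 1.0, 0.8 — distinct so component matching is
  unambiguous; absolute scale is a free parameter, as no amplitude
  scale is reported), multiplied by a per-component factor on post-drug
  conditions (default 0.9/0.7/0.9: all components reduced, alpha most,
  matching the study's qualitative readout).
* **Noise** — i.i.d. Gaussian on tensor entries, SD expressed as a
  fraction of the noiseless signal RMS (default 5%); the simplest
  exchangeable model consistent with z-scored inputs. A Laplace switch
  provides a heavier-tailed variant.
* **Raw epochs** — per channel, a sum over components of carrier
  oscillations at each component's spectral peak, envelope following
  its temporal profile, amplitude set by its topography, and a uniform
  random phase per trial and component — so power is induced, not
  evoked — plus broadband Gaussian noise (default SD 30% of the
  amplitude scale).

What the synthetic experiments show: the estimation machinery recovers
factor-structured ground truth (matched Tucker congruence ≥ 0.95 on all
five modes at 5% noise across seeds), the permutation test is calibrated
and powerful under the generator's assumptions, and all printed
bookkeeping arithmetic is reproduced. What they do not show: performance
under real EEG violations — volume-conducted correlated noise,
non-Gaussian artifacts, non-multilinear interactions (e.g.
frequency-shifting components), or imperfect trial cleaning. The
generator's multilinear-plus-noise world is exactly the CP model's
favourable case.

## Problem sizes and defaults used in the checks

The acceptance suite runs the decomposition checks on a 16×12×20×8×4
tensor (same structure, desk scale) and the permutation operating
characteristics on 200 replicate 8×6×10×6×4 datasets × 200 permutations
each — sizes chosen so the full suite completes in minutes while the
binomial bands on the measured rates stay tight. The bookkeeping
quantities (entry count 9,636,536; 621 = 3×(61+31+98+13+4) free
parameters, <0.01% of entries; the 42×201 pre-crop and 31-bin post-crop
grids) are computed at the study's full printed sizes. One open
bookkeeping point: 40..1000 ms at 10 ms steps gives 97 bins, while the
printed grid says 98; the generator's time axis uses 40–1010 ms so that
both the printed bin count and step size hold, and the TF chain reports
whatever its crop actually produces.

## Known limitations

* Active-set enumeration restricts ranks to ≤ 12 per fit — ample for
  component analysis of this kind, not for large-rank completion tasks.
* CORCONDIA on noisy high-order collinear data is uninformative (see
  above); explained-variance plateaus plus component inspection carry
  the rank choice there, as they did in the original study.
* The permutation test treats slabs as the exchangeable unit; it does
  not model trial-level variability (trials are averaged before
  tensorisation).
* No missing-data handling: flagged TF bins must be cropped or trimmed
  before decomposition.
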