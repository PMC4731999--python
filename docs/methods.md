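# Methods

`sclmi` implements the complete computational analysis of a sequential
compound limb motor-imagery (SCL-MI) EEG experiment — ERSP/ERD
quantification, mu-band phase-locking analysis, and two four-class decoders —
together with a synthetic-EEG generator that reproduces the paradigm's
statistical structure with known ground truth, so that every stage carries a
parameter-recovery test.  This note records the model, the defaults and why,
the numerical conventions, and the limits of what the synthetic studies show.

## Paradigm

Four imagery sequences of three sub-movements each: RRR, RLR, LFL, FRL
(R = right hand, L = left hand, F = right foot), drum-paced under two
conditions — condition 1 with 1-s sub-movement slots inside 8-s trials
(3 s of imagery after a 3-s circle/cue period, 2 s rest), condition 2 with
2-s slots inside 12-s trials.  All analysis time axes are relative to
imagery onset (cue offset).  Slot windows are half-open `[start, end)` so
the three slots tile the imagery period without double-counting boundary
samples.

Sub-movement *roles* label hand slots 2-3 by their prior limb: RH_PH_I/II/III
and RH_PF_I for the right hand (measured at C3), LH_PH_I/II and LH_PF_I for
the left (at C4).  Roman numerals are assigned in order of first occurrence
scanning RRR, RLR, LFL, FRL with slot 2 before slot 3 — the figure-level
source does not print the assignment, and only stable labels matter for the
paired tests.  The phase-locking analysis partitions all twelve
(sequence, slot) cells into initial (slot 1) and non-initial (slots 2-3)
groups per limb; the partition is asserted exhaustively in the tests.

## Synthetic generator

Each channel is background 1/f noise (power spectral density proportional to
1/(f+1), 5 µV rms) plus a white floor (1 µV rms); HEO/VEO carry
low-frequency noise (30 µV) and exist so the 62-channel exclusion rule is
exercised.  C3, Cz, C4 and FCz additionally carry band-limited noise
carriers: a mu carrier (7-13 Hz, 12 µV rms — chosen to span the full 8-13 Hz
measurement band so a band-averaged ERD value equals the injected
attenuation, and large enough that in-band background, ~1.9 µV², does not
bias phase or power estimates) and a beta carrier (16-30 Hz, 8 µV).
Narrow-band *noise* carriers rather than sinusoids keep ERSP bandwidths and
Burg spectra realistic.

**ERD.** During a slot, the carrier amplitude at the active limb's
contralateral electrode (C3/C4 for the hands, Cz for the foot) is multiplied
by sqrt(g), where g ∈ (0, 1] is the configured power attenuation — default
0.5 for the hands (a typical ~50 % sensorimotor power drop) and 1.0 for the
foot (no foot ERD at Cz, matching the reported phenomenology; configurable).
A hand slot whose predecessor was also a hand slot is deepened to
`g ** prior_hand_boost` (default boost 1.4), the ground truth behind the
prior-limb contrast.  The step profile of sqrt-depths is smoothed with a
100-ms Hann kernel, giving cosine-like ramps centered on slot boundaries;
contiguous equal-depth slots (e.g. RRR) therefore form one continuous
attenuation block.

**Phase coupling.** The FCz mu component is, during each slot, a phase-
jittered copy of the active central electrode's analytic mu signal:
`Re[z(t) · exp(i·theta(t))]`, where theta(t) has exactly a von Mises(0, κ)
marginal (Gaussian AR(1) mapped through the probability transform) with
correlation time τ = 0.1 s.  κ defaults to 2 for initial and 5 for
non-initial slots.  τ matters: the asymptotic time-averaged PLV of this
construction is I₁(κ)/I₀(κ), but jitter faster than the 8-13 Hz analysis
band is smoothed away by the filter (inflating PLV), while slower jitter
inflates the finite-window modulus bias; τ = 0.1 s balances the two so that
the measured mean PLV at κ = 2 and κ = 5 reproduces the closed form within
±0.03 at 70 trials.  Outside coupled slots FCz carries its own independent
mu carrier, cross-faded at slot edges.

Spatial spread adds fixed-weight copies of each source's signal to
neighbouring electrodes (e.g. C3 → C1/C5/FC3/CP3 at 0.4), so CSP has
non-trivial spatial structure.  All randomness derives from one seed through
named `SeedSequence` substreams; identical parameters give bit-identical
recordings.

**What is not emulated:** volume conduction beyond fixed leakage weights,
ocular/muscle artifacts, inter-subject variability, slow nonstationarities,
mains interference, and post-imagery ERS rebound (an optional overshoot gain
exists, default off, since the origin of the reported long-lasting ~10 Hz
synchronization is unclear).  Passing recovery tests therefore show the
*estimators* are correct and calibrated, not that real EEG meets their
assumptions.

## Preprocessing

Optional zero-phase 50-Hz notch (off for synthetic data, which has no
mains), FIR anti-aliased decimation to 200 Hz with event-index rescaling,
common average reference over the 62 scalp channels (EOG excluded — the
reference set is not specified at the source, and non-scalp channels do not
belong in a scalp average), and zero-phase 4th-order Butterworth band-passes
(forward-backward, ≥30 dB one octave out of band) — zero-phase because any
group delay would corrupt the phase-locking analysis.  Epochs are cut at
(−3, 5) s or (−4, 8) s around imagery onset with half-open sample ranges;
trials clipped by the recording edges are dropped and counted, never padded.
Band-pass filtering for the decoders is applied to epochs with the filter's
reflection padding guarding the edges.

## ERSP and ERD values

Per trial, short-time Fourier power on a Hanning window of 256 samples
(condition 1) or 512 samples (condition 2) at 200 window centers evenly
spanning the epoch (centers rounded to the nearest sample; no zero-padding,
so the bin spacing is 0.78125 / 0.390625 Hz).  Trial-averaged power is
converted to decibels against the per-frequency mean power over the
pre-onset baseline (3 s / 4 s): divisive baseline normalization, the
standard ERSP convention — the source text does not state the variant, and
subtractive normalization is deliberately not offered.  Maps are cropped to
1-30 Hz.  An ERD value is the arithmetic mean of the dB map over a
rectangle, membership by bin center, half-open on both axes; the role
analysis uses the fixed 8-13 Hz alpha band (configurable) over the role's
slot window.

**Temporal dilution.** The STFT window (1.28 s / 2.56 s) is longer than one
slot (1 s / 2 s), so windows centered inside a slot mix in signal from
outside it.  For a slot embedded in a contiguous attenuation block (RRR),
mid-slot estimates are undiluted and the recovery studies show the measured
value matches 10·log₁₀(g) closely; for a temporally isolated attenuation
(e.g. the hand slot of FRL), the slot-mean estimate is biased toward zero by
roughly 0.6 dB at g = 0.5.  This is a real property of the measurement
scheme, not of the generator: roles differ in temporal context, so measured
role ERDs differ slightly even when injected depths are identical.  At the
12-dataset × 10-trial scale of the paired-contrast study this bias is small
against between-dataset variability and the null battery rejects at
approximately the nominal rate, but at much larger trial counts the paired
tests would resolve the dilution difference itself.

## Phase-locking values

Phases are analytic-signal angles of 8-13 Hz filtered epochs, computed on
the whole epoch and sliced to the slot window so edge transients cannot bias
slot estimates (stand-alone phase extraction reflection-pads and trims).
The single-trial PLV is the modulus of the within-slot mean unit phasor of
the phase difference; trial-averaged PLVs are arithmetic means of per-trial
values, and the initiality contrast pools per-trial values across a limb's
cells (maximizing degrees of freedom) using the limb's designated pair
(C3-FCz, Cz-FCz, C4-FCz).

**Finite-sample floor.** The per-trial time-averaged PLV of two *unrelated*
band-limited signals does not vanish: with ~5 Hz of bandwidth and a ≤2-s
window there are only ~10-20 independent phase samples, giving a null floor
of ≈0.3 (≈ sqrt(π/2)/sqrt(N_eff)).  The recovery studies reproduce
I₁(κ)/I₀(κ) within ±0.05 for κ = 2 and κ = 5, where the asymptotic value
dominates the floor, but no time-averaged estimator on these windows can
reach the asymptotic value 0 at κ = 0; the κ = 0 measurement reports the
floor, and the corresponding acceptance check documents this as expected
behaviour of the estimator class itself.

## Multi-class CSP decoder

Per trial, the spatial covariance is trace-normalized (standard practice;
removes amplitude confounds) and averaged within class.  The composite
covariance is whitened, P = Λ^(−1/2) U₀ᵀ; per class, Yᵢ = P Σᵢ Pᵀ is
eigendecomposed (one-vs-rest), rows of Wᵢ = Uᵢᵀ P sorted by descending
eigenvalue, eigenvector signs fixed by making the largest-magnitude entry
positive.  The eigenvalue pairs of Yᵢ and its complement sum to one — an
exact identity asserted in every fit.  Features are log variances of the
first l projections per class; the classifier is a linear SVM (C = 1,
one-vs-one), chosen for determinism and comparability with the RFE pipeline.
Filter-count selection over l ∈ {1, 2, 3, 4} happens inside the same
tenfold stratified CV with shared folds (paired selection), replicating the
protocol's own scheme; its optimism is documented rather than silently
corrected (chance-level estimates therefore average over the grid instead of
taking its maximum).  Because CAR leaves the scalp-channel mean identically
zero, the composite covariance of referenced data is rank-deficient by one;
the estimator performs reduced-rank whitening (null eigendirections dropped;
every identity holds on the retained subspace), while the low-level
`whitening()` operation rejects deficient input by default, reporting the
deficient dimension count.

## PSD decoder with grouped SVM-RFE

The imagery period is cut into 200-sample segments stepped by 100 (m = 5 /
11 segments for the two conditions).  Each segment is fit with an order-5
autoregressive model by Burg's recursion — implemented vectorized over all
trials × channels × segments for speed and verified per-segment against an
independent reference implementation — and its spectrum, evaluated on a
512-point one-sided grid, is summed over delta/theta/alpha/beta/gamma bands
(half-open `[lo, hi)`), giving 5·m features per scalp channel (1550 and
3410 columns).  The gamma band's 50 Hz edge coincides with the acquisition
notch of real recordings; the generator has no mains line, so no special
handling beyond this note.

Channel selection treats each channel's columns as a group: a linear
one-vs-one SVM is fit on column-standardized surviving features, channel
importance is the sum of squared weights over the channel's columns and all
binary machines (the canonical SVM-RFE criterion; the source names none),
and the lowest-importance channel is removed — one per iteration, ties
broken toward the channel later in montage order.  The ranking is produced
once on the full data and the accuracy-vs-channel-count curve is then
evaluated by tenfold CV per count (the two-stage protocol as described;
feature standardization is refit inside every training fold, enforced by a
leak-canary test).  Constant feature columns are dropped from the importance
computation with a warning.

## Statistics

Paired t-tests for the five planned role contrasts (RH_PH_I/II/III vs
RH_PF_I; LH_PH_I/II vs LH_PF_I); a median-centered Levene test at α = 0.05
selecting pooled vs Welch two-sample t-tests for the initial/non-initial PLV
contrast (the homogeneity test is unnamed at the source; Levene with median
centering is the robust default); a two-sample t-test for the
condition-accuracy comparison.  All tests two-sided; no multiplicity
correction by default (mirroring the protocol), Holm available behind a
flag.  Significance stars at 0.05 / 0.01.  Zero-variance degenerate inputs
are rejected (paired) or force the Welch branch with a flag (two-sample).

## Study problem sizes

The recovery studies use the protocol's 70 trials per class; ERD and PLV
recovery use condition 2, whose 2-s slots give the estimators the most
degrees of freedom per slot (the generator's own worked example is stated at
condition 2).  The paired-contrast battery uses 12 subject-equivalent
datasets (the cohort size of the original study) of 10 trials/class per
seed, with boost 1.6 in the detection arm so the planned contrasts are
resolvable at that per-dataset size.  Decoder studies use 70 trials/class at
erd_depth 0.2 for the strong-separability check and 20 trials/class at
default depths for the method comparison.  Large simulations are generated
directly at the 200 Hz analysis rate; the 1 kHz acquisition-rate path with
FIR decimation is validated separately on short recordings.

## Known limitations

* The generator's coupling and ERD are confined to exact slot windows with
  100-ms ramps; real ERD onset/offset dynamics are slower and asymmetric.
* The temporal-dilution bias described above means measured role ERDs are
  not perfectly exchangeable under the generator null; it is inherent to
  fixed-length STFT windows longer than the analysed slot.
* The per-trial time-averaged PLV estimator has a non-vanishing null floor
  on short windows; contrasts are valid, absolute values near zero are not.
* CV-based filter-count and channel-count selection inside the evaluation
  loop is optimistically biased; a nested scheme is available but is not the
  default, to mirror the replicated protocol.
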