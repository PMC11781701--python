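# Methods

## Problem and pipeline

The package decodes a driver's braking intention — hard braking, soft
braking, or normal driving — from simultaneous EEG (16 channels, 10–20
sites) and EMG (8 leg/arm muscles) sampled at 1000 Hz. The decoding chain
is, per binary subproblem: common spatial patterns (CSP) → temporal or
spectral features → distance-correlation feature selection → regularized
LDA with a piecewise-linear probability map → optional EEG/EMG fusion →
one-vs-rest or decision-tree multiclass assembly. Evaluation is offline
(stratified sixfold cross-validation on 1 s epochs) and pseudo-online
(1 s window sliding in 60 ms steps over a continuous held-out recording).

## Preprocessing

Order is fixed: Butterworth bandpass (EEG 0.5–60 Hz, EMG 15–90 Hz; `order`
counts poles per band edge so the passband is flat to <1% at mid-band) →
decimation to 200 Hz → linear artifact suppression on EEG → per-epoch
baseline correction (mean of the first 100 ms ≙ 20 samples at 200 Hz) →
common average reference. Offline filtering is zero-phase
(forward–backward); the bandpass is applied at the raw rate to maximize
anti-aliasing margin, and decimation uses a linear-phase FIR anti-alias
filter.

The pseudo-online stream path must not look ahead, so it uses causal
single-pass filters (IIR decimation for low group delay) over the whole
stream once; baseline correction and CAR are applied per window, exactly as
a real-time decoder would. The causal chain delays detections by tens of
milliseconds relative to the zero-phase path — visible as smaller (sometimes
negative) advanced times at default noise levels. This is a deliberate
fidelity/latency trade-off, not a defect; the offline and stream paths are
covered by a consistency check on separable data.

Artifact suppression replaces interactive independent-component screening
with a deterministic rule: FastICA (seeded; fitted on a uniform subsample of
at most 40 000 points for speed) decomposes the 200 Hz EEG, and components
whose absolute Pearson correlation with the frontal-channel mean (F3, Fz,
F4) exceeds 0.7, or whose power fraction below 3 Hz exceeds 0.6, are zeroed
before remixing. The fitted unmix→mask→remix matrix is stored and reapplied
verbatim to test streams. The suppressor is fitted once per continuous
training session before epoching, which is standard for unsupervised
artifact cleaning; classifier-level train/test separation is enforced at the
trial level. Rank-deficient or too-short input falls back to the identity
with a warning.

## CSP

Per-epoch covariances are trace-normalized (E = XXᵀ/tr XXᵀ), making the
decomposition invariant to global amplitude scaling. Class-mean covariances
receive a relative ridge of 1e-6·tr/C·I before the mixed covariance
Em = Ēt + Ēn is formed: common-average-referenced data are exactly
rank-deficient along the channel-mean direction, and the ridge keeps the
whitener G = Λm^(−1/2) Fmᵀ finite. All stored invariants (G Em Gᵀ = I,
λt + λn = I) are algebraic identities in the ridged matrices and hold to
1e-8. Eigenvector signs are fixed by making each filter's largest-magnitude
entry positive; equal eigenvalues break ties by original index. The retained
projection keeps the m/2 rows with the largest and m/2 with the smallest
target eigenvalue — the canonical symmetric CSP choice. Multiclass problems
fit one CSP per binary dichotomy (one-vs-rest or the cascade's two tasks),
the standard two-class extension.

## Features and selection

Temporal EEG features are the projected amplitudes themselves; temporal EMG
features are the linear envelope (rectification, then a zero-phase
second-order 2 Hz Butterworth low-pass — the cut-off is read as 2 Hz,
standard linear-envelope practice). Spectral features are one-second
rectangular-window periodograms (no detrending, so Parseval holds exactly);
at 1 s windows the bins are integer frequencies and band restriction keeps
bins in [low, high] inclusive — the 0.5 Hz lower EEG edge maps to bin 1
since no sub-Hz bin exists. EEG bands δ(0–4), Θ(4–8), α(8–13), β(13–30),
γ(30–50) and the full 0.5–60 Hz are selectable; EMG spectral features use
15–90 Hz.

Selection scores every scalar feature by its sample distance correlation
with the ±1 label vector: pairwise absolute differences are double-centered
and dCor = dCov/√(dVar(A)·dVar(B)), with dCov/dVar the square roots of the
mean products of the centered matrices. Zero-variance features score 0 by
convention; ranking ties break toward the lower index; W is clamped (with a
warning) to the available feature count. Scores are fitted on training folds
only and the frozen index list is reused on test folds. The hyperparameter
grids m ∈ {2,…,16 step 2}, M ∈ {2,…,8 step 2}, W ∈ {10,…,100 step 10} are
honored by an optional inner-CV selection harness
(`evaluate.select_hyperparameters`); default configurations fix m=6, M=4,
W=30 (mid-grid) so that desk-scale runs finish in minutes — the full
per-fold grid search is available through the experiment config.

## Classifier

ψ = Σω′⁻¹(v₁−v₂) — the printed form "Σω′/(v₁−v₂)" is read as the standard
regularized discriminant, since dividing a matrix by a vector is undefined.
Σω is the pooled within-class covariance (divisor n−2), ω = tr(Σω)/g, and
Σω′ = (1−λ)Σω + λωI. λ is selected from 0.1…1.0 (step 0.1) by inner
stratified 5-fold CV accuracy on the training data, ties toward smaller λ.
The decision threshold is the midpoint of the projected class means
(prior-free, deterministic; configurable). Probabilities are the
piecewise-linear stretch anchored at (thre, ½) and the *global* training
extrema ymax/ymin (per-class extrema were the alternative reading; global is
used), clamped to [0,1]; a threshold at a training extremum degrades to the
saturated constant with a warning.

## Fusion and multiclass

Feature-level fusion (FL) min-max-normalizes each modality's selected
features with training-fold extrema (test values clipped to [0,1]; a
constant feature maps to 0 with a warning) and concatenates EEG-then-EMG
into one RLDA. Classifier-level fusion combines per-modality probabilities:
AND (both ≥ ½), OR (either ≥ ½), or naive-Bayes with equal priors
(likelihood products p₁p₂ vs (1−p₁)(1−p₂); exact ties — including
conflicting saturated probabilities — resolve to nontarget, the conservative
choice for a braking alarm). Because one-vs-rest needs comparable *scores*,
the CL rules also expose min(p₁,p₂), max(p₁,p₂) and the normalized
posterior respectively, each consistent with its decision rule at 0.5.
Sequential models assign whole binary stacks to one modality: SE1 uses EEG
for hard-vs-rest and EMG for everything else (including normal-vs-rest under
one-vs-rest assembly), SE2 swaps.

One-vs-rest compares the three binary probabilities (raw ψᵀx scores are not
on a common scale across independently fitted models) and resolves exact
ties with priority hard > soft > normal — safety first, and configurable.
The decision tree tests hard-vs-rest then soft-vs-normal with strict ">"
comparisons; the thresholds K1/K2 default to 0.5 on the probability scale,
which is exactly the binary models' own threshold pushed through the
monotone probability map.

## Evaluation

Offline: seeded stratified sixfold CV (15 epochs per fold, 5 per class at
default conditions); every fitted stage (CSP, selector, normalizer, RLDA)
sees training folds only. Pairwise AUCs are rank-based on pooled test-fold
probabilities.

Pseudo-online: windows end every 60 ms; a braking event is hit if any window
whose decision matches the event's class ends within (stimulus,
stimulus + 1.2 s]; one hit per event, and the advanced time is the pedal
onset minus the end of the *earliest* detecting window (window end is the
instant all evidence is available). The false-positive denominator — which
the protocol leaves open — is windows lying entirely inside normal-driving
segments, i.e. outside [stimulus, pedal onset + 2 s] of every braking event;
a wrong-class decision during an event is a miss, not a false positive.
System accuracy uses the complement form Sa = 1 − (Fal + (1−Hit_e) +
(1−Hit_s))/3: the form with raw hit rates in the numerator decreases as
detection improves, which contradicts its use as a quality score, so it is
treated as a typographical slip and kept available behind
`printed_form=True`.

## Synthetic sessions

The simulator emulates the study conditions the pipeline assumes: 60 trials
per subject (30 hard), 15 s trials, raw rate 1000 Hz, braking stimulus
12.0–12.8 s into the trial, reaction time lognormal with median 700 ms and
σ = 0.2 (no distribution is prescribed; the median follows the design
default and σ keeps ~95% of reactions within the 1.2 s hit window). Class
activity precedes the pedal-deflection marker by 300 ms (±20 ms jitter) in
both modalities.

EEG is 1/f background (10 µV RMS) plus a 10 Hz posterior alpha rhythm and,
on braking trials, a transient of band-limited noise packets with
class-specific band gains and scalp topography (hard: delta/theta-heavy,
central; soft: weaker, alpha-tilted, parietal) — no biophysical head
modelling, since the pipeline only assumes class-conditional second-moment
differences. EMG is 15–90 Hz noise (5 µV RMS) plus a trapezoidal-envelope
burst with class-specific per-muscle amplitudes; carriers are independent
across muscles (uncorrelated motor-unit activity), which also means CAR does
not cancel the bursts. Hard braking is plantar-flexor-dominant, soft braking
a weaker dorsiflexor-weighted pattern — distinct in pattern, not only scale,
so the intermediate class is linearly separable from both neighbors.
Frontal blink-like bumps (300 ms raised-cosine, ~35 µV, 0.1/s) exercise the
artifact-suppression stage. `complementary_profiles()` provides a diagnostic
variant in which EEG carries only hard-vs-rest and EMG only soft-vs-normal
information, isolating what fusion buys.

All randomness flows from one seed through named substreams (trial timing,
reaction, EEG/EMG noise, responses, artifacts, normal-epoch placement), so
identical config + seed is bit-identical and any one source can be pinned.

What the simulator does **not** emulate: volume-conduction-realistic
topographies, non-stationary background, mains interference (the 50 Hz notch
hook exists but the generator injects none), ocular/cardiac artifact
morphology beyond the generic low-frequency bumps, subject-to-subject
variability structure, or EEG/EMG cross-correlation. Passing tests therefore
demonstrate the *pipeline's* correctness and its behavior under controlled
signal-to-noise, not expected performance on human recordings.

## Problem sizes and numerical choices

Default analyses use 90 offline epochs per subject (30/30/30), sixfold CV,
and 20-trial held-out sessions (~5000 sliding windows) for pseudo-online
replay; the acceptance script averages three virtual subjects. Covariance
ridge 1e-6 (relative); probability map clamped; degenerate min-max spans map
to 0; singular mixed covariances regularized with ε = 1e-10·tr/C and a
logged warning. Monte-Carlo checks (chance-level control, fusion benefit)
use ≥20 seeded replicates; the chance-level control reshuffles labels of one
simulated subject rather than re-simulating, which is the sharper
permutation null for the same budget.

## Known limitations

- CL1/CL2 one-vs-rest scores (min/max of probabilities) are a package
  convention; any monotone surrogate consistent with the AND/OR tables would
  do, and ranking-sensitive results could differ.
- The pseudo-online causal chain introduces group delay, so advanced times
  are systematically smaller than the neural/myoelectric lead; comparisons
  between models remain valid since all share the chain.
- The inner-CV λ selection is per binary stack; no joint calibration across
  stacks is attempted.
- EDF output quantizes to 16 bits over each channel's observed range.
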