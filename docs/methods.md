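# Methods

This note documents the models, procedures and numerical choices behind
`laminaprobe`: what each simulator emulates, what each analysis assumes,
and where the design was genuinely open.

## 1. EPSP model (in vitro, subthreshold)

A compound EPSP evoked from one stimulation site is a difference of
exponentials,

    V(t) = A · [e^{-(t-t0)/τ_d} − e^{-(t-t0)/τ_r}] / k ,   t ≥ t0,

normalized so the peak equals the amplitude `A`.  The analytic peak time
relative to onset is `τ_r τ_d/(τ_d − τ_r) · ln(τ_d/τ_r)`, which tends to
the alpha-function peak (`t* → τ`) as `τ_r → τ_d`.

Defaults (ms, mV): deep input `τ_r = 1.5`, `τ_d = 15`, onset 1.0,
amplitude 6; superficial input shares `τ_d` and amplitude, its onset is
0.2 ms later, and its rise constant is solved by root-finding (brentq)
so the somatic peak-time difference between sites is exactly **2.0 ms**.
The onset split is a free calibration — the stimulus artifact obscures
onsets in real recordings, so only the sum (onset + rise effect) is
constrained; we attribute a small fraction to onset and the rest to
dendritic filtering.  Population simulations multiply rise constants and
amplitudes by lognormal cell factors (shared between sites within a cell,
since dendritic geometry is a cell property; CVs 0.06 and 0.15) and add
Gaussian recording noise (0.05 mV default).

EPSP measurement follows the recording convention: amplitude is the peak
of the averaged trace minus the mean voltage near the 70 ms post-stimulus
reference, peak time is reported relative to the stimulus, and the first
time-derivative over 2–12 ms is returned for rise-rate comparison.
Passive properties come from hyperpolarizing steps: R = ΔV/I from the
steady state; τ from a linear fit to log(remaining deflection) over the
initial charging segment (10–90 % by default).

## 2. Evoked spiking (in vitro, population)

A cell fires when the noiseless deep EPSP crosses its threshold
(threshold mean 4 mV, SD 0.5 mV across cells).  The superficial
first-spike latency is the deep latency plus the calibrated
`superficial_extra_delay` (**0.6 ms** default) — the quantity the
generator must reproduce, applied directly rather than re-derived from
kinetics.  Cyclical local re-excitation produces later response waves at
multiples of `i_wave_period` (1.7 ms) with emission probabilities
(0.9, 0.5, 0.25) per wave; later waves share their timing between sites
(only the first wave distinguishes superficial from deep input).  Each
cell also carries a base-latency offset (SD 0.1 ms, conduction and
synaptic-distance heterogeneity) and each spike a trial jitter
(SD 0.25 ms).  Default 200 trials per site, matching typical evoked
recording practice (100–200 stimuli per site).

Two calibration facts matter for the shuffle test:

* the trial jitter makes each cell's PSTH a smooth ~0.3 ms-wide bump, so
  averages of shuffled cell mixtures vary continuously rather than
  flipping between two resolved sub-peaks;
* the cross-cell spread is kept below the 0.6 ms effect so the population
  first peak stays sharp, as the method presupposes.

With negligible jitter the first-peak statistic becomes discrete
(multiples of the 0.1 ms bin) and a permutation test on it is
hyper-conservative; with much larger cross-cell spread the band-passed
waveform of group averages becomes multi-lobed and peak assignment
bistable.  The defaults sit deliberately between those regimes.

## 3. PSTH analysis and the Monte Carlo latency test

PSTHs use 0.1 ms bins over 0–10 ms, per-cell normalization by trial
count, then equal-weight averaging across cells (cells, not trials, are
the unit).  Band-passing uses a 2nd-order Butterworth 400–2000 Hz filter
run forward–backward (`sosfiltfilt`, odd-reflection padding), so measured
latencies carry no group delay; this emulates the filtering that tissue
applies between a population spike response and the epidural field it
generates.

"First peak" is operationalized as the first local maximum after a
0.5 ms artifact-blanking interval whose height **and** topographic
prominence both exceed 25 % of the post-blanking global maximum; the
prominence requirement rejects low-lying filter ripple that clears the
height threshold.  Peak times are refined below the bin width by a
parabolic fit through the peak bin and its neighbours (a symmetric peak
is returned unchanged); this makes the latency continuous, so permutation
p-values are tie-free.  All thresholds are configurable.

The Monte Carlo test randomly reassigns the per-cell PSTHs to two groups
of the original sizes, re-averages, re-filters and re-measures, 1000
times; `p = (#{|Δnull| ≥ |Δobs|} + 1)/(N+1)`, two-sided by default with
the one-sided value also reported.  Shuffles whose filtered average has
no qualifying peak are dropped; more than 10 % of them aborts the test
with a diagnostic.  Test calibration is checked on the test's own
exchangeability null — datasets whose cell labels have been randomly
permuted — where the rejection rate at α = 0.05 is 0.044 over 500 runs
and the p-distribution is uniform.  Note that a generator null that
merely sets the site effect to zero is *not* exchangeable: both sites
share each cell's base latency, the observed difference is then nearly
zero while shuffling breaks the pairing, and the test is conservative by
construction (this mirrors how the test behaves on real paired data).

## 4. Epidural volleys (in vivo)

Traces are Gaussian bumps (σ = 0.12 ms) for the D wave (latency 2.0 ms,
depth-independent) and the I1 wave, whose latency follows a configurable
depth map: by default the D–I1 interval grades linearly from 1.9 ms at
the cortical surface to 1.4 ms at the deepest contact (16 contacts,
150 µm spacing), so the shallowest I1 is **0.5 ms** later than the
deepest and all intervals stay in the physiological 1.4–2.0 ms band.
Intensity scales amplitude mildly (5 %/mA) but not latency.  Each
(depth, intensity) block carries a common timing drift (SD 0.02 ms)
emulating slow preparation drift; without it the within-block variance of
measured latencies is essentially zero and a one-way ANOVA flags
microsecond-level interpolation artifacts as depth effects.  D/I1
measurement band-passes the averaged trace, takes D as the first
qualifying peak and I1 as the next qualifying peak ≥ 1 ms later, flagging
a missing I1 rather than failing.

## 5. Motoneuron pool and H-reflex conditioning

Thresholds of the `n_units = 120` motoneurons are truncated-normal
(mean 1.0, SD 0.3, floor 0.05, arbitrary excitability units).  The
afferent volley arrives at a fixed spinal time and contributes a drive
calibrated by root-finding so the expected unconditioned recruitment
fraction — the model's H/Mmax — is 20 %, the midpoint of the 15–25 %
target band.  TMS at delay `d` (TMS fires at PNS − d; negative = TMS
after PNS) launches four descending components: `deep_early` at offset
0 ms (strength 0.15), `superficial_late` at +0.6 ms (0.10), and two
later waves (+1.7, +3.4 ms).  A component adds its strength when its
spinal arrival falls within the 2 ms temporal-summation window ending at
the afferent arrival.  With the default conduction (10.5 ms) and afferent
arrival (14.0 ms), the fastest component first coincides at
**EFD0 = −3.5 ms**, and recruitment grows stepwise as the delay becomes
less negative — temporal summation of successive volleys.

Fired units add a biphasic Hanning-windowed MUAP at the afferent arrival
plus a per-unit efferent delay (normal, mean 3.5 ms, SD 0.3 ms).  The
MUAP duration is 3.0 ms: with a kernel shorter than the delay spread,
positive and negative lobes of overlapping units cancel and compound
amplitude stops growing with recruitment, violating the intended
monotonicity of H-reflex size in recruited count; 3 ms keeps the first
0.5 ms of the reflex inside the constructive first phase.  Trial noise
enters as a common drive term (SD 0.04), small per-unit noise (0.02) and
EMG noise (3 µV at 10 kHz); a small fixed M-wave (8 % of Mmax at 6.5 ms)
precedes the reflex.

## 6. H-reflex quantification and the EFD search

Reflex onset is determined once per dataset from the across-trial mean
rectified unconditioned EMG: the first time within a 10–40 ms
post-stimulus window that it exceeds the pre-stimulus baseline mean plus
3 SD, sustained 0.3 ms (an automated stand-in for per-subject visual
onset determination; a manual override is honoured verbatim).  Each
trial's H-reflex is the RMS of the *unrectified* EMG over
[onset, onset + 0.5 ms) — 5 samples at 10 kHz — after subtracting the
value at the onset sample (baseline-offset correction); background EMG is
the mean rectified activity over the 50 ms before the stimulus.  The
0.5 ms window confines the measure to the earliest, monosynaptic reflex
component.

The two-step search uses the rough grid (−5…−2 ms, 0.5 ms steps,
7 delays + unconditioned, 15 randomized blocks) and a fine grid of 11
delays at 0.1 ms spacing anchored at the rough hit.  Following the
worked-example geometry, the fine grid extends toward *more negative*
delays (anchor −1 ms … anchor); a flag flips the direction, since the
procedure's verbal description is ambiguous on this point.  A delay is
the earliest facilitation when its paired t-test (by block) against the
unconditioned reflex is significant (p < 0.05, uncorrected — the
three-delay rule is the procedure's own multiplicity guard) with
conditioned > unconditioned, and the next two scheduled delays are also
significantly higher.  Hits within the last two schedule positions are
returned with an edge flag rather than discarded.  If the fine stage
finds nothing, the rough hit was most likely a chance positive one step
before the true onset (its successors are then genuinely facilitated, so
the compound rule cannot reject it); the fine grid is re-anchored at the
next significant rough delay, at most twice, before giving up.  Over 100
simulated subjects with true onsets uniform in [−4.5, −2.5] ms the
search recovers EFD 0 ms to within 0.1 ms in ≈ 98 % of runs at default
noise.

## 7. Adaptive task and simulated observer

The dot-motion difficulty controller is a weighted up/down staircase per
difficulty: after a correct response coherence decreases by
`step·(1 − target)`, after an error it increases by `step·target`
(step 1 % coherence).  Its zero-drift equilibrium is exactly
P(correct) = target, so the difficult staircase converges to **55 %** and
the easy one to **80 %**.  The observer is a 2AFC logistic psychometric
function of coherence (c50 30 %, slope 8 %, lapse 0.02) with a linear
c50 decline of 6 percentage points over the session (perceptual
learning), which the controller tracks — coherence trajectories fall over
a session while accuracy stays at target.  Convergence at default
settings: last-1000-trial accuracy within ±3 points of target in a
4000-trial session.

## 8. Composed experiment and task-epoch analysis

A probed session crosses epochs × {unconditioned, EFD0, EFD+0.6} ×
{difficult, easy}, 20 trials per cell, pseudo-randomized; cue direction
comes from the task trials (≈ balanced).  Task-state modulation enters as
multiplicative gains on circuit strengths keyed by (epoch, difficulty,
direction); the default boosts `superficial_late` by 1.6 for easy flexion
cues at the cue+400 ms epoch only — the magnitude is unconstrained by
the timing data (only sign and epoch/effector specificity), so 1.6 was
fixed once as a moderate effect.  Reaction-time EMG bursts follow the
fixation-offset marker with easy-cue responses faster than difficult
(173 vs 226 ms means); a configurable fraction of trials carries inflated
background EMG.

Analysis: trials whose 50 ms pre-stimulation background exceeds the
resting-session mean + 2 SD are excluded (flagged, with reason, not
dropped).  Reaction time is the first sustained (10 ms) excursion of the
rectified EMG above baseline mean + 4 SD after fixation offset, evaluated
on a 5 ms moving-average envelope — the sustain requirement on raw
rectified samples is statistically unsatisfiable, so the envelope carries
it.  Facilitation is conditioned/unconditioned × 100 % from per-subject
means; the unconditioned reference is pooled per probing epoch (it is
cue-independent in the model), so cue-specific contrasts share a
denominator and its sampling noise cancels in paired comparisons.  Cue
modulation is facilitation(easy)/facilitation(difficult) × 100 %.
Pre-planned families (epoch × delay condition, per experiment and cue
direction; family size 4 by default) are tested with paired t-tests; raw
p-values are reported with a Bonferroni-adjusted significance flag, and
Lilliefors normality / Levene homogeneity p-values attached as
diagnostics, not gates.

## 9. What the synthetic data do and do not show

The generators reproduce the *statistical structure* the analyses need:
calibrated latency splits, recruitment-driven EMG with realistic trial
variability, staircase dynamics, epoch/effector-specific gain modulation,
contaminated-trial exclusion.  They do not model biophysical membrane
dynamics, spinal interneuron circuitry, post-activation depression,
motor-unit size ordering (thresholds and conduction delays are drawn
independently), volume conduction, or task kinematics.  Passing tests
therefore demonstrate that the analysis pipeline recovers known ground
truth under realistic noise — not that the physiological claims hold in
new recordings.

## 10. Problem sizes and determinism

Defaults were chosen so the full test suite runs in a couple of minutes
on one core: 24 spiking cells × 200 trials/site, 32 subthreshold cells,
1000-shuffle tests (500-run calibration), 100 simulated EFD subjects,
13–14 subjects × 2 simulated experiments for the task analysis.  Every
simulator takes a seed or Generator; pipelines spawn per-stage child
streams from one root seed (recorded in the run manifest together with
config snapshot and output digests), so identical config + seed reproduce
outputs bit for bit.
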