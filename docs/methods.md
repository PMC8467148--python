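# Methods

This note describes the models and procedures implemented in `ecgdx`, the
parameters that matter, and what the synthetic test bed does and does not
establish about behaviour on real recordings.

## Scope and label space

The toolkit implements a knowledge-based (rule-based) multi-label classifier
for 12-lead ECGs over the 24 scored diagnostic classes used by the
PhysioNet/CinC Challenge 2020 scoring system, together with the
continuous-wavelet scalogram representation used as input for image CNNs, the
Challenge evaluation metrics, and class-balancing subset construction.  The
three equivalent diagnosis pairs (complete RBBB / RBBB, PAC / supraventricular
premature beats, PVC / ventricular ectopic beats) are merged into single
columns; the SNOMED CT codes in `ecgdx/data/class_vocabulary.csv` are
externally sourced configuration (the public Challenge code list) and can be
edited without touching code.  CNN training itself is out of scope: the
scalogram module's contract ends at the 224 x 224 x 3 image plus a label
manifest.

## Preprocessing

Signals are converted to mV on read (per-lead gain/baseline from the header)
and resampled to a common 500 Hz by polyphase filtering.  Noise suppression
is deliberately conservative so amplitude-based features stay honest:

* **Mains**: zero-phase IIR notch, default 50 Hz (configurable to 60), Q = 30.
* **Baseline wander**: two-stage moving-median subtraction (200 ms, then
  600 ms).  The first stage straddles the QRS without following it, the
  second rejects P/T waves, so the cascade tracks sub-0.5 Hz wander while
  leaving ST-T morphology untouched.
* **No low-pass on the signal path.**  Muscle-noise smoothing (40 Hz
  zero-phase Butterworth) is applied only to the detection velocity channel.

## QRS detection

Detection follows the spatial-velocity principle: the mean over selected
leads (default II and V1) of the absolute first difference times the sampling
rate, in mV/s.  Candidate regions must exceed a combined threshold
`max(0.4 x rolling 99th percentile over 10 s, 10 mV/s)`.  Two design points
were settled empirically on the synthetic bed:

* A mid percentile over a short window straddles the QRS/baseline boundary
  when the QRS duty cycle is near the percentile's tail mass, and
  fibrillatory-wave velocity can ride above it.  A high percentile over a
  long window stays pinned to QRS velocity both on records carpeted with
  f-waves and on records with one outsized ectopic beat.
* A velocity-consistency pass drops detections whose velocity peak is below
  40% of the median detection peak; these are filter edge transients or
  baseline spikes, not beats.

Detections are refined to the extremum of the RMS deflection across all
leads within ±60 ms, a 200 ms refractory interval is enforced, and polarity
is taken from the dominant lead at the fiducial (R positive, S negative).
The detector is amplitude-scale invariant down to the absolute velocity
floor.

RR statistics use successive differences in ms; the standard deviation uses
population normalisation (the variability bands the rules quote are tight,
and the estimator choice is stated rather than left implicit).  Heart rate
is 60000 / mean RR.

## Median beat

Beats are aligned on the fiducial in a [-400, +600] ms window.  A beat is
rejected when its fiducial RMS amplitude deviates more than 30% from the
median R amplitude or its correlation with the median template falls below
0.9 — a concrete reading of "signal-averaging of the sustained beats";
survivors are combined sample-wise by median.  If everything is rejected the
single most template-like beat is returned with a quality flag.

## Delineation and features

QRS onset/offset are found by walking outward from the fiducial on the
grey-closed (12 ms structuring window) RMS velocity across leads until it
stays below threshold for 16 ms.  The threshold is the largest of: 5% of the
QRS velocity peak, 1.5x the beat's own quiet-zone velocity (95th percentile
of the window fringes), and 2 mV/s.  The adaptive term matters on
fibrillation-like records, where residual atrial waves in the median beat
would otherwise hold the search open.  T end uses the classical tangent
method: the steepest tangent of the dominant T wave's terminal limb
intersected with the baseline.  When the mean RR is known, the T search is
capped at 62% of it and the atrial search window at 45%, so at fast rates
the neighbouring beats' waves cannot masquerade as T or P.

The descriptor set mirrors the rule engine's vocabulary: per-beat QRS
peak-to-peak amplitudes (lead II); RR mean/std; derivative zero-crossing
counts inside the QRS (max over V1-V4, 10 ms smoothing) and per RR interval
between beats (lead II, 20 ms smoothing, blanking -20/+80 ms around the
QRS, 2 uV/ms hysteresis); P-wave presence by a 20 uV significant-peak test
in [QRS onset - 400 ms, onset - 40 ms] on leads II then V1, with PR measured
from the 20 uV departure point; Q-wave existence (>= 25 uV and >= 10 ms);
predominant-R (>= 95% of absolute QRS area positive, leads I/V6); ST-T
displacement opposite the dominant QRS deflection in V5; M/W-shaped QRS by
piecewise-linear segmentation (turning points pruned below 50 uV, two
principal same-sign peaks); the frontal-plane axis as `atan2(aVF, I)` at the
instant of maximal frontal vector magnitude, clockwise-positive degrees in
[0, 360) so the printed right-axis [90, 180] and left-axis [270, 330] bands
apply verbatim; amplitude ratios Q/R (lead I) and R/S (max over II/III,
absent denominators giving +inf, which no "<" condition can satisfy); the
initial-QRS slope as the absolute amplitude change over the first 30 ms
divided by 30 (max over leads); T-wave sign in V1-V3.

Choices the underlying rule set leaves open, fixed here and stated: the
inside-crossing count is taken on the leads the bundle-branch rule inspects
(V1-V4, maximum); the outside count on lead II; PR is measured from P onset
rather than P peak.

## Rule engine

The rules are evaluated in a fixed order (regularity, rate, flutter /
fibrillation, conduction, axis, pacing, intervals, voltage, T waves) so
later rules can read earlier outputs; the fibrillation rule, evaluated after
flutter, overrides it when its stronger waviness condition (> 15 crossings
per interval vs > 9) holds — the pair is mutually exclusive by construction.
The flutter/fibrillation gate `PAC > 0.7` is strict: the soft PAC score 0.7
(RR std in [35, 46] ms) does not open it; only RR std > 46 ms does.

All thresholds are carried as printed, including three that sit far from
conventional clinical cut-offs: first-degree AV block at PR > 130 ms,
prolonged PR at > 110 ms, and long QT at > 340 ms with no rate correction.
A consequence the user should expect: a textbook-normal PR of 160 ms fires
both PR-interval rules.  The engine also scores the normal rhythm class 1
for *any* record whose RR variability and QRS amplitudes are unremarkable —
it is a knowledge-base simplification, not a bug, and it is kept as printed.
Classes with no printed rule (NSIVCB, QAb, Tab) always score 0.  An
undefined feature makes every condition reading it false; classification is
total and pure.  Per-class provenance records every fired rule for audit.

## Scalogram generation

The CNN input series concatenates 10 s of the eight independent leads
(I, II, V1-V6; short records cyclically tiled, long ones truncated) with the
same leads' median beats.  The continuous wavelet transform uses the
generalized Morse wavelet, built in the frequency domain as
`Psi(w) ~ w^beta exp(-w^gamma)` for `w > 0` (exactly analytic), with
symmetry `gamma = 3` and time-bandwidth product `P^2 = beta * gamma = 60`,
hence `beta = 20`; scales are geometric with 12 voices per octave, spanning
from just below Nyquist down to the lowest frequency whose wavelet support
fits the series.  The magnitude is normalised per image, resized bilinearly
to 224 x 224, and mapped through a configurable colormap ("jet" default —
the reference figures suggest a dark-to-bright map but name none;
pixel-exact figure replication is a non-goal).  Per-image normalisation
makes the rendering invariant to uniform amplitude scaling; JPEG encoding
(quality 95) is the final step so all tests assert on raw pixels.

## Evaluation

Per-class F-beta and G-beta follow the printed competition formulas
(`F_b = (1+b^2)TP / ((1+b^2)TP + FP + b^2 FN)`,
`G_b = TP / (TP + FP + b FN)`), macro-averaged over classes that occur.
AUROC/AUPRC are delegated to scikit-learn and cross-checked in the test
suite against exhaustive threshold enumeration.  The weighted score uses
the Challenge's modified confusion allocation: each record spreads unit
credit over true x predicted label pairs normalised by the union size, the
reward matrix weights it, and the sum is normalised between an inactive
classifier (always the normal class, score 0) and a perfect one (score 1).
The numerical reward matrix is configuration (CSV); the identity matrix is
the built-in default, under which the raw credit reduces to
intersection-over-union accuracy.

## Class balancing

Under-sampling retains a record while any of its labels is below the
per-class cap, visiting records in seeded-random order; multi-label records
can therefore spill a capped class above the cap, which is the qualitative
behaviour of the published learning subsets (exact subset replication would
require the original RNG stream and is a non-goal).  Over-sampling tops
minority classes up to a target by drawing duplicates with replacement.
Both use an explicit PCG64 stream keyed by the seed.

## Synthetic test bed

The generator builds template beats — raised-cosine P/QRS/T lobes, plus a
sum-of-Gaussians rSR' ("M") template for bundle-branch morphologies — on an
RR grid drawn from a truncated normal and affinely standardised so the
realised RR mean and standard deviation equal the programmed values exactly.
That standardisation is what makes tight recovery tolerances meaningful at
10-20 s record lengths: the sample deviation of ~11 raw draws would
otherwise exceed the tolerance band by itself.  Limb leads are hexaxial
projections of a programmed frontal vector; the T lobe is placed so that
its steepest-tangent intersection lands exactly at the programmed QT; the
P onset convention matches the detector's 20 uV departure point to within
its analytic offset.  Presets cover every class with a printed rule.  Two
stylisations are deliberate: the flutter/fibrillation presets use baseline
sinusoids at 8 and 13 Hz — chosen to separate the > 9 and > 15
crossings-per-interval thresholds cleanly, not to mimic clinical atrial
rates — and the pacing preset uses a 24 mV spike because the printed
initial-slope threshold (0.7 mV/ms over 30 ms) is unreachable by any
physiological amplitude.  The normal-rhythm preset programs PR 110 ms and
QT 310 ms, below the printed interval thresholds, so that an unremarkable
record fires only the normal class.

What passing the synthetic suite shows: the signal-processing chain
recovers programmed rhythm and morphology parameters within stated
tolerances (mean RR 2%, RR std max(5 ms, 20%), QRS ±10 ms, PR ±25 ms,
QT ±20 ms, axis ±10°), and each rule fires on records constructed to
satisfy it.  What it does not show: performance on real ECGs, which have
beat-to-beat morphology variation, wandering electrode noise, genuinely
ambiguous rhythms and multi-label pathology that no template generator
reproduces.  The published validation score of the rule set on the real
hidden Challenge data (~0.32-0.33) is the realistic expectation, not the
near-perfect synthetic coverage.

## Problem sizes and numerical conventions

Default runs use 10 s records at 500 Hz (the under-sampling demonstrations
use a few hundred synthetic label rows); these sizes keep the full test bed
fast while leaving every stage's behaviour observable.  Sample indexing is
0-based with `t = index / fs`; all internal amplitudes are mV; intervals ms;
angles clockwise-positive hexaxial degrees.  Degenerate inputs (flat
records, absent T waves, truncated atrial windows, all-zero scalograms,
empty label matrices) degrade to flagged undefined values rather than
exceptions throughout.
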