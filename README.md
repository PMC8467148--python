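# ecgdx

Rule-based diagnostics for 12-lead ECGs, Morse-wavelet scalogram images, and
multi-label evaluation over the 24-class scored arrhythmia label space of the
PhysioNet/CinC Challenge 2020.

The package is aimed at people building or benchmarking automatic ECG
interpreters: it provides (1) a transparent expert-system classifier whose
every decision is auditable, (2) the time-frequency image representation
used to train image CNNs on ECGs, (3) the competition's metrics, and (4) a
synthetic 12-lead generator so the whole pipeline runs and is testable
without downloading any clinical data.

## What it computes

**Rule-based classifier.**  After mains-notch and baseline-median filtering,
QRS complexes are detected from the *spatial velocity* (mean absolute first
derivative over selected leads) with a combined adaptive/absolute threshold;
a robust median beat is formed by outlier-rejecting signal averaging; QRS
onset/offset and T end (tangent method) are delineated; and a descriptor
vector is extracted — RR mean/std, per-beat QRS amplitudes, derivative
zero-crossing counts inside/outside the QRS, P-wave presence and PR
interval, QT interval, M/W-shaped QRS, frontal-plane axis, amplitude ratios,
initial-QRS slope, T polarity.  A fixed-order list of if–then rules maps the
descriptors to per-class scores in [0, 1]; e.g. the fibrillation/flutter
pair is separated purely by irregularity (RR std > 46 ms) plus the rate of
derivative zero-crossings between QRS complexes (> 15 vs > 9 per interval),
and the two rules are mutually exclusive by construction.

**Scalograms.**  Ten seconds of the eight independent leads plus their
median beats are concatenated and transformed with an exactly analytic
generalized Morse wavelet (symmetry 3, time-bandwidth product 60, 12 voices
per octave); the coefficient magnitude is rendered as a 224 x 224 x 3 image.

**Evaluation.**  Per-class confusion counts, F1 / F2 / G2 by the printed
competition formulas, AUROC/AUPRC, and the reward-weighted normalized
Challenge score (identity reward matrix built in, official matrix loadable
from CSV).

**Balancing.**  Seeded random under-sampling with a per-class cap (multi-
label aware) and random over-sampling of minority classes.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

```python
from ecgdx import analyze_record, generate, preset

rec, truth = generate(preset("af", seed=1))   # synthetic atrial fibrillation
res = analyze_record(rec)

f = res.features
print(f"{len(res.peaks)} beats; mean RR {f.mean_rr:.0f} ms, "
      f"RR std {f.std_rr:.1f} ms")
print(f"crossings/interval outside QRS: {f.n_cross_outside_qrs}")
print({k: v for k, v in res.scores.scores.items() if v >= 0.5})
print(res.scores.provenance["AF"])
```

prints

```
10 beats; mean RR 1000 ms, RR std 79.7 ms
crossings/interval outside QRS: 20
{'IAVB': 1.0, 'AF': 1.0, 'PAC': 1.0, 'LPR': 1.0, 'SA': 1.0}
['PAC > 0.7 and n_cross_outside_QRS 20 > 15']
```

The record is highly irregular (RR std 79.7 ms fires the irregularity rule
at full score) and the baseline between QRS complexes is carpeted with
fibrillatory waves (20 derivative zero-crossings per RR interval, above the
fibrillation threshold of 15), so AF is asserted and flutter suppressed.
The extra labels are honest rule-engine behaviour, not noise: an irregular
rhythm also satisfies the sinus-arrhythmia rule, and the fibrillatory waves
in the atrial window look like P waves to the 20 µV significance test, which
drags the PR-interval rules along — exactly the kind of knowledge-base
brittleness the per-class provenance makes visible.

The same pipeline is scriptable from the shell:

```bash
ecgdx simulate af -n 5 --seed 1 --out demo/records
ecgdx classify demo/records --out demo/labels
ecgdx scalogram demo/records --out demo/images
ecgdx evaluate demo/records/truth.csv demo/labels/… # see --help
```

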