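# fetalstress

Analysis toolkit for detecting chronic maternal stress from maternal and
abdominal (composite maternal + fetal) ECG, combining two complementary
methods:

1. **Fetal stress index (FSI)** via bivariate phase-rectified signal
   averaging (BPRSA).  Maternal heart rate (mHR) is the *trigger* series and
   fetal heart rate (fHR) the *target*: anchor points are placed at mHR
   decreases, 2L-sample windows of the interpolated fHR are aligned at the
   anchors and averaged into the curve X, and

       FSI = 1/(S2-S1) * [ sum_{i=L+S1}^{L+S2} X(i) - sum_{i=L-S2}^{L-S1} X(i) ]

   with L = 9000 samples at 900 Hz (a 20 s window), S1 = 1350 (1.5 s) and
   S2 = 2250 (2.5 s).  FSI quantifies how strongly the fetal heart rate is
   entrained by maternal decelerations — a biophysical marker of chronic
   prenatal stress.

2. **Self-supervised ECG affect recognition.**  A multi-task 1-D
   convolutional network learns ECG representations without labels by
   recognizing which of six signal transformations (noise addition, scaling,
   negation, temporal inversion, permutation, time-warping) a 10-s / 256 Hz
   segment underwent.  The convolutional trunk is then frozen and small
   fully connected heads are trained to classify the stress group (binary
   cross-entropy) and to regress hair cortisol, FSI, PDQ and PSS-10 (mean
   absolute error), evaluated with a within-subject 5-fold protocol and the
   full accuracy / F1 / sensitivity / specificity / PPV / NPV / AUROC panel.

The clinical recordings this analysis was designed for are private, so the
package ships a fully documented synthetic cohort generator
(`fetalstress.synthetic_data`) with known ground truth: maternal PQRST
waveforms with LF/HF heart-rate variability, a weaker faster fetal ECG
coupled to maternal decelerations with a tunable gain, an additive
abdominal mixture, per-second signal-quality indices with artifact epochs,
and group-conditional PSS/PDQ/cortisol labels.  Everything downstream runs
identically on real single-channel ECG imported via CSV or the HDF5
container (`fetalstress.pipeline_io`).

## Worked example

```python
import numpy as np
from fetalstress import (
    BPRSAConfig, CohortConfig, HeartRateSeries, compute_fsi, generate_cohort,
)
from fetalstress.synthetic_data import HRVParams, couple_fetal_rr, generate_rr_series

# a 40-minute mother-fetus dyad with strong coupling
m_beats = generate_rr_series(80, HRVParams(), 2400, np.random.default_rng(42))
maternal = HeartRateSeries(m_beats)
f_beats = couple_fetal_rr(maternal, coupling_gain=2.0, lag=0.5,
                          fetal_base_hr=140, rng=np.random.default_rng(43),
                          duration=2400)
res = compute_fsi(maternal, HeartRateSeries(f_beats))
print(f"FSI = {res.fsi:.4f} from {res.n_anchors} anchors")
```

prints

```
FSI = -0.2210 from 1129481 anchors
```

The negative sign says the fetal heart rate is *lower* after maternal
decelerations than before them — the fetus tracks the maternal
deceleration.  With the coupling gain set to 0 the same seeds give
FSI = -0.0462, roughly five times closer to zero; |FSI| increases
strictly with the ground-truth gain (Spearman rank correlation 1.0 across
gains 0, 0.25, 0.5, 1.0, 2.0).

The learning pipeline at desk scale:

```python
from fetalstress import TransformationRecognitionEncoder, generate_cohort
from fetalstress.preprocess import build_segment_dataset
from fetalstress.evaluate import evaluate_task

recs, truth = generate_cohort(CohortConfig(n_subjects=40, recording_minutes=10, seed=0))
ds = build_segment_dataset(recs, truth, role="mECG")
enc = TransformationRecognitionEncoder(epochs=4, random_state=0).fit(ds.X)
panel = evaluate_task(ds, enc.state_, "classify_stress", k=5, random_state=0, epochs=150)
print(panel[panel.level == "segment"][["fold", "accuracy", "auroc"]])
```

On this synthetic cohort the held-out segment-level AUROC is ~0.96-0.98
over the five folds; FSI regression on the same folds reaches R2 ~0.55
(near the information ceiling set by the 10-minute FSI estimation noise —
predicting FSI from the *true* coupling gain gives R2 ~0.56 on this
cohort).

A command-line interface mirrors the stages:
`fetalstress simulate | preprocess | fsi | pretrain | run`.

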