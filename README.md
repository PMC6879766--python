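# cardioahi

Estimation of the apnea–hypopnea index (AHI) from single-lead ECG, for
researchers in cardiorespiratory sleep monitoring who want an unobtrusive
surrogate for polysomnography-derived OSA severity.

Obstructive sleep apnea produces a characteristic cardiovascular
signature: a progressive bradycardia during each airway obstruction and a
sharp post-event tachycardia, accompanied by arousal-related movement.
`cardioahi` detects 30-second epochs surrounding respiratory events
(*RE-epochs*) from heart-rate-variability and ECG-movement features, then
converts the detected epoch fraction into an AHI.

## Method

1. **Epoch labelling.** An epoch is an RE-epoch when a single respiratory
   event overlaps it by ≥ 10 s, or when it starts < 5 s after an event
   ends (the "after event" rule, capturing the bradycardia–tachycardia
   aftermath).
2. **Features.** R peaks are detected with a Hamilton–Tompkins-style
   detector; inter-beat intervals (IBIs) outside 0.5–2 s are rejected, and
   consecutive-interval ratios > 1.5 tag ectopic pairs. Per-epoch features
   are computed on windows centred on each epoch (HRV time statistics and
   spectral powers on 300 s, detrended fluctuation exponents on 360 s,
   multiscale entropy on 540 s, ECG activity counts on 30 s), subject to
   IBI-coverage rules.
3. **Feature optimisation.** Each feature is transformed per recording by
   a greedy chain (≤ 5) drawn from a 22-transformation catalogue with a
   group-connection graph, maximising the absolute mean standardized
   distance between classes,
   `AMSD = |μ_RE − μ_nonRE| / σ_all`.
4. **Classification and calibration.** An elastic-net logistic classifier
   (SGD-trained, SMOTE+ENN-balanced) yields per-epoch RE probabilities.
   The AHI is `AHI_pred = β · (#detected RE epochs) / (#sleep epochs)`,
   with β the Theil–Sen slope regressing reference AHI on the true
   RE-epoch fraction, and the probability threshold chosen by maximising
   Cohen's kappa between estimated and reference severity
   (normal/mild/moderate/severe at 5/15/30 events/h).
5. **Evaluation.** Spearman correlation, Bland–Altman bias and limits of
   agreement, ±30 events/h outlier flags, Breusch–Pagan
   heteroscedasticity, screening ROC/kappa at the canonical thresholds,
   and severity confusion matrices.

A fully annotated synthetic-data generator (hypnogram, events, IBI series
with event-locked responses, ectopic beats, template ECG rendering)
makes every stage testable without clinical data.

## Worked example

Simulate a small population, train, and score a held-out recording:

```sh
cardioahi simulate --n 8 --seed 5 --out data/
cardioahi train --data data/ --seed 5 --out model.bundle
cardioahi predict --model model.bundle --ibi data/sim000_ibi.csv \
    --hypnogram data/sim000_hypnogram.txt --out pred
```

The train step reports the fitted calibration and the predict step the
estimate:

```
trained logistic_elastic_net: beta=96.56, threshold=0.96
sim000_ibi: AHI_pred=0.67 (normal)
```

(`sim000` was generated with a true AHI of 3.6 events/h — both sides of
the normal/mild boundary.) The predict step writes `pred_epochs.csv`
(per-epoch RE probability and class) and
`pred_ahi.json` (AHI, severity, epoch counts). Library use mirrors the
CLI: `generate_population` → `prepare_recording` → `train_pipeline` →
`predict_recording`.

## End-to-end validation run

`scripts/acceptance.py` re-runs the whole method from scratch: it
simulates a severity-balanced population (40 training + 20 held-out
recordings of 2 h), trains the estimator, predicts the held-out
recordings and prints the agreement and screening summaries:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints, for example:

```
model: logistic_elastic_net, beta 97.60, probability threshold 0.90
held-out n=20: Spearman rho 0.928, bias 0.63 events/h, LoA [-17.45, 18.70]
  AHI >= 5: kappa 0.73, sens 93%, spec 80%, AUC 0.97
  AHI >= 15: kappa 0.90, sens 90%, spec 100%, AUC 1.00
  AHI >= 30: kappa 0.47, sens 60%, spec 87%, AUC 0.88
severity accuracy 65%
```

Here `beta` converts the detected RE-epoch fraction to events/h, the
Bland–Altman bias is the mean reference-minus-estimate difference, and
the per-threshold rows summarise OSA screening at the canonical severity
cut-offs.

## Scope notes

ECG input is read from EDF (one channel by label); pre-computed IBI
series can be supplied as CSV to bypass ECG processing. Respiratory-event
annotations use a plain CSV schema (`kind,onset_s,duration_s,
desaturation_pct,arousal`), hypnograms one sleep/wake token per line.
Sleep/wake staging itself is out of scope — the stage sequence is an
input. See `docs/methods.md` for model details, defaults and known
limitations.
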