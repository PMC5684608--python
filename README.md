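# preictal

Patient-specific epileptic seizure prediction from multichannel scalp EEG.

Seizure prediction rests on the hypothesis that a *preictal* state — a
transition period before seizure onset — is electrophysiologically
distinguishable from the normal *interictal* state. `preictal` implements a
classical realisation of that idea for CHB-MIT-style recordings (18–23
channels at 256 Hz) and is aimed at researchers who want a transparent,
fully tested reference pipeline they can run end to end without clinical
data:

1. **Framing** — the multichannel signal is cut into overlapping epochs of
   length *L* = 3 s with a 1 s step (overlap *L* − 1).
2. **Common spatial patterns (CSP)** — per-epoch normalized covariances
   `C = DDᵀ / trace(DDᵀ)` are averaged per class into `C₁` (preictal) and
   `C₂` (interictal); the composite `C_c = C₁ + C₂` is whitened with
   `P = ψ^(−1/2) F_cᵀ` from `C_c = F_c ψ F_cᵀ`, and the whitened class
   matrices are simultaneously diagonalized, `S₁ = U Λ₁ Uᵀ`,
   `S₂ = U Λ₂ Uᵀ` with `Λ₁ + Λ₂ = I`. The projection `W = Uᵀ P` holds one
   spatial filter per channel.
3. **Features + classifier** — the natural log of each filtered row's
   variance gives an *N*-element feature vector (23 × 1 for a 23-channel
   montage) feeding a closed-form LDA trained on
   randomly undersampled, class-balanced epochs.
4. **Alarms** — the 1 Hz binary decision series is smoothed with a
   seventh-order median filter; an alarm fires when a run of consecutive
   preictal decisions first reaches a patient-specific threshold α,
   selected on training data.
5. **Evaluation** — alarms are scored against prediction horizons of
   60/90/120 min: sensitivity (predicted / evaluable seizures),
   false-waiting-time specificity `spec = 1 − fwt/np`, false prediction
   rate per hour, and prediction time, with periodic and Poisson
   chance-level predictors as baselines. A 10-min postictal interval and
   10-min margins around recording gaps are excluded throughout.

A synthetic EEG generator (`preictal.synth`) produces multichannel
Gaussian recordings whose interictal/preictal spatial covariances differ by
a controllable separation, so the entire pipeline — including leave-one-
recording-out cross-validation — runs and is tested without any download.

## Worked example

Evaluate the full predictor by leave-one-recording-out on a synthetic
6-record set (10 min per record, 8 channels, covariance separation 1.5):

```bash
cat > demo.toml <<EOF
n_records = 6
record_min = 10.0
channels = 8
separation = 1.5
fs = 64.0
seed = 11
EOF
preictal loocv --synthetic demo.toml --horizon-min 60 --seed 1 --out demo_run
```

prints the cross-validation average

```
 sensitivity  specificity  fpr_per_h  mean_prediction_time_min
         1.0          NaN        0.0                  1.033333
```

Every held-out seizure was predicted (sensitivity 1.0) with no false alarms
(0 per evaluated hour), and the earliest positive alarm preceded onset by
about a minute on average. Specificity is NaN here by construction: with
10-minute records and a 60-minute horizon every instant lies inside some
seizure's prediction horizon, so no "normal interval" exists and the
false-waiting-time ratio is undefined — the per-round details are in
`demo_run/rounds.csv`. A rate-matched Poisson baseline for comparison:

```bash
preictal baselines --synthetic demo.toml --kind poisson --seed 1 --out demo_bl
```

Other subcommands: `simulate` (write synthetic records as `.npz` fixtures),
`train` / `evaluate` (fit once, score elsewhere), and `loocv --data-dir
<dir> --summary-file <summary.txt>` for real EDF record sets with
CHB-MIT-style seizure annotations.

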