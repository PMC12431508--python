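# cokurt

Real-time anomaly detection for multivariate wearable health streams,
built on higher-order joint cumulants: per-window (heart-rate, steps)
observations are scored against a healthy reference distribution via a
**cokurtosis tensor → HOSVD → feature-moment-metric → Hellinger
distance** pipeline. The package also ships a weight-clipped **WGAN**
that produces per-user digital twins of the joint (heart rate, steps)
distribution, and a **Latin-hypercube perturbation** loop that grows a
synthetic population cohort from a handful of users. Everything is
testable offline through the built-in synthetic cohort simulator.

## Method sketch

1. **Stream processing** (`cokurt.stream`) — a time-sensitive queue
   aggregates a per-minute stream into sliding windows (length *w*,
   slide *s*) and extracts latent features: resting (RHR), active (AHR)
   and overall (OHR) heart rate plus step totals.
2. **Reference grid** (`cokurt.detector`) — an integer lattice *H* over
   the healthy (heart-rate, steps) ranges observed in a calibration
   span. Each window's observation *D* = (RHR, step total) is appended
   (*H′ = H ∪ D*); both sets are standardized, their cokurtosis cumulant
   tensors factorized by HOSVD, the spectra collapsed into
   feature-moment-metric vectors (discrete distributions over features),
   and the Hellinger distance between them is the anomaly score. A
   window alerts when the score exceeds the threshold Δ (default 0.008).
   A personalized RHR bound ∇ (90th percentile of 24–48 h of history,
   clipped to [90, 110] bpm) supports patient-level evaluation.
3. **Evaluation** (`cokurt.evaluate`) — patient-level confusion
   matrices, F1 / false-negative rate, and (Δ, ∇) grid sweeps with 90%
   empirical confidence bands.
4. **Digital twins** (`cokurt.wgan`) — a Wasserstein GAN (single hidden
   layer of 256 LeakyReLU(0.2) units per network, 100-dimensional
   Gaussian noise, tanh generator output, critic weights clipped to
   [−0.01, 0.01], RMSProp) trained until the per-channel empirical
   Wasserstein-1 distances between real and synthetic RHR/AHR/OHR
   distributions fall below tolerance. Implemented directly on numpy —
   no deep-learning framework required.
5. **Synthetic populations** (`cokurt.lhs`) — stratified (Latin
   hypercube) standard-normal perturbations of a real user's normalized
   data (*P = R + εL*), re-scaled and fed to the WGAN; converged
   snapshots at least 1000 epochs apart are harvested as cohort members.

## CLI

All commands are under a single entry point:

```bash
# synthetic cohort: wearables CSV + ground-truth sickness intervals
cokurt simulate --users 60 --days 28 --sick-fraction 0.33 --seed 1 --out cohort/

# score a wearables CSV (user,datetime,heart_rate,steps) into alerts
cokurt detect --input cohort/cohort.csv --labels cohort/labels.csv \
    --window 60 --slide 30 --delta 0.008 --adaptive-rhr --out alerts.csv

# WGAN digital twin of one user (+ JSON convergence trace sidecar)
cokurt twin --input cohort/cohort.csv --user U000 --seed 1 --out twin.csv

# LHS-perturbed synthetic population from real users
cokurt population --users cohort/cohort.csv --epsilon 0.01 --epsilon 0.03 \
    --realizations 5 --seed 1 --out pop/

# (delta, nabla) uncertainty sweep over alert scores
cokurt evaluate --alerts alerts.csv --labels cohort/labels.csv \
    --delta-range 0.005 0.02 --rhr-range 90 110 --out sweep.csv

# end-to-end: simulate -> detect -> evaluate with a manifest
cokurt pipeline --users 60 --seed 1 --out run/
```

### File formats

| file | columns |
|---|---|
| wearables CSV | `user, datetime (ISO-8601), heart_rate (bpm), steps (count/min)` |
| labels CSV | `user, onset, end` (sickness intervals) |
| features CSV | `user, window_start, window_end, rhr, ahr, ohr, step_total, n_minutes, flags` |
| alerts CSV | `user, window_start, window_end, rhr, steps, score, threshold, is_anomaly` |
| sweep CSV | `delta, nabla, f1, fnr` |

## Module map

| module | role |
|---|---|
| `cokurt.moments` | standardization, cokurtosis cumulant tensor, HOSVD, FMM, Hellinger |
| `cokurt.stream` | sliding-window queue, latent RHR/AHR/OHR features |
| `cokurt.detector` | reference grid, anomaly scores, alerts, adaptive RHR bound |
| `cokurt.evaluate` | confusion matrices, F1/FNR, threshold sweeps with CI bands |
| `cokurt.wgan` | numpy WGAN (weight clipping), PDF-distance convergence, twins |
| `cokurt.lhs` | Latin-hypercube sampling, ε-perturbation, population loop |
| `cokurt.simulate` | synthetic cohort generator + toy outlier datasets |
| `cokurt.io` / `cokurt.cli` / `cokurt.pipeline` | CSV formats, CLI, orchestration |
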