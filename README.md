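# respigate

Respiratory-signal forecasting and gating-latency feasibility analysis
for respiration-gated radiotherapy.

## The problem

Gated radiotherapy delivers the beam only inside preselected respiratory
phases (typically the 30%-70% window of each breathing cycle), driven by
a 1-D surrogate signal measured on the patient's chest at 20 Hz. The
beam-control chain reacts with a latency of 300-800 ms, so the gating
decision must be based on a *forecast* of the surrogate: given the last
`T_s` milliseconds of signal, predict its value `P_t` milliseconds ahead,
where `P_t` matches the machine latency.

`respigate` implements that pipeline end to end:

1. **Synthetic cohorts** — quasi-periodic Lujan-type `cos^2n` breathing
   traces with controlled per-cycle period jitter, amplitude jitter,
   baseline drift and noise, in four regularity classes (`regular`,
   irregular period `type1`, irregular amplitude `type2`, both `type3`).
2. **Preprocessing** — per-signal Z-scoring, stride-1 sliding
   (window, target) pairs, temporal 7:3 train/validation splits with
   whole signals held out for test, Savitzky-Golay smoothing of
   predicted series.
3. **Irregularity taxonomy** — the irregularity value
   `(STD(peaks) + STD(valleys))/2` on extremum amplitudes and on cycle
   periods, and rank-based assignment of four equal disjoint groups.
4. **Predictors** — LSTM, bidirectional LSTM and an encoder-decoder
   Transformer (8-head scaled dot-product attention, look-ahead masking,
   one-position decoder offset), trained with Adam (lr 1e-4, weight
   decay 2e-4, batch 300, MSE) and best-validation checkpointing, on an
   in-package NumPy autodiff core.
5. **Evaluation** — per-signal RMSE and Pearson CC, one-way ANOVA across
   models, and sweeps over `T_s` and `P_t`.
6. **Gating feasibility** — phase decomposition of each breathing cycle
   (0% at peak inhale), 30%/70% gate times on the predicted signal, and
   the absolute amplitude error in millimetres after scaling the record
   to a 10-mm tumor excursion, per latency (300/500/700 ms).

## Worked example

```python
from respigate.study import run_reference_study

study = run_reference_study(seed=1)
for kind in ("lstm", "bilstm", "transformer"):
    print(f"{kind:12s} regular-test CC {study.regular_test_cc(kind):.4f}  "
          f"test RMSE {study.mean_test_rmse(kind, 500):.4f}  "
          f"gating mm @300/500/700: "
          + "/".join(f"{study.feasibility_mean_error(kind, l):.2f}"
                     for l in (300.0, 500.0, 700.0)))
```

prints (seed 1, ~15 min on one CPU):

```
lstm         regular-test CC 0.9901  test RMSE 0.1654  gating mm @300/500/700: 0.21/0.44/0.51
bilstm       regular-test CC 0.9893  test RMSE 0.1786  gating mm @300/500/700: 0.21/0.45/0.51
transformer  regular-test CC 0.9914  test RMSE 0.1775  gating mm @300/500/700: 0.23/0.45/0.86
```

Reading: under the standard condition (`T_s` 1000 ms, `P_t` 500 ms) all
three predictors track regular synthetic breathing with CC near 0.99;
accuracy degrades as the forecast horizon grows (at `P_t` = 900 ms the
test RMSE rises to 0.36 / 0.33 / 0.27 for LSTM / Bi-LSTM / Transformer,
the transformer degrading least); amplitude-irregular breathing hurts
prediction more than period-irregular breathing for every model; and
the millimetre gating error at the 30%/70% phases grows monotonically
with latency for every model — mirroring the clinical conclusion that
feasibility hinges on the machine's latency and on the patient's
amplitude regularity.

The command-line interface exposes each stage
(`respigate simulate / classify / train / evaluate / sweep /
feasibility`) and a one-shot `respigate run --config experiment.yaml`
that writes metrics tables, checkpoints and a SHA-256 manifest;
identical configs reproduce byte-identical manifests.

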