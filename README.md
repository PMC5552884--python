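# hbci — confidence-weighted group decisions from EEG and response times

`hbci` implements a hybrid brain–computer interface (hBCI) for augmenting
group decision making in rapid visual-search tasks. Each group member makes
a binary decision `d ∈ {+1, −1}` ("target present / absent"). The hBCI
estimates, per trial, the probability `w ∈ [0, 1]` that the decision is
correct — the member's *decision confidence* — from two sources:

* **neural features** — the log-variance of stimulus-locked and
  response-locked EEG epochs projected onto the leading Common Spatial
  Patterns (CSP) filter, trained to contrast correct vs incorrect trials;
* **a behavioural feature** — the response time, which is reliably longer
  on incorrect, low-confidence decisions.

A correctness-trained, L2-regularised logistic model maps the feature
vector of participant *p* on trial *i* to the weight `w_{p,i}`, and the
group decides by weighted majority:

```
G_i = sign( Σ_p  w_{p,i} · d_{p,i} )
```

with exact-zero sums (ties) resolved by a fair coin flip. Because even-sized
groups tie exactly when members disagree, confidence weighting acts as a
principled tie-breaker and lifts group accuracy above plain majority voting.

The package is aimed at researchers studying collaborative BCIs, confidence
estimation, and the wisdom of crowds under communication. Human recordings
for this paradigm are not publicly deposited, so the package ships a
synthetic-cohort simulator that reproduces the statistical structure the
pipeline relies on (8 blocks × 40 trials with exactly 25% targets, shared
stimulus sequences, correctness-dependent response times and ERP
amplitudes, confidence reports that decouple from correctness when members
communicate), making every stage testable end to end.

## What's inside

| module | contents |
|---|---|
| `hbci.simulate` | `SimulationConfig`, `simulate_session`, `simulate_cohort` — synthetic EEG + behavioural tables |
| `hbci.preprocess` | earlobe re-referencing, 0.15–40 Hz FIR band-pass, ocular regression, 1900 ms epoch extraction, conditioning to 48 samples at 32 Hz |
| `hbci.features` | `CSPTransformer` (sklearn-style), log-variance neural features, feature-vector assembly |
| `hbci.confidence` | `ConfidenceEstimator` — logistic confidence weights with inner-CV selection of C |
| `hbci.groups` | weighted majority rule, tie-breaking, subset and pair-preserving group enumeration |
| `hbci.evaluate` | shared 10-fold CV harness, Wilcoxon/Kruskal–Wallis contrasts, ERP grand-average contrasts, moving-average dynamics |

## Worked example

Simulate an isolated 10-participant cohort at a reduced 16-channel /
128 Hz montage and run the full cross-validated evaluation:

```python
from hbci import SimulationConfig, simulate_cohort, run_pipeline_cv

config = SimulationConfig(n_participants=10, n_channels=16,
                          sampling_rate=128.0, seed=1)
sessions = simulate_cohort(config)
result = run_pipeline_cv(sessions, methods=("majority", "hbci"),
                         sizes=(1, 2, 4), seed=1)
print(result.table.groupby(["method", "size"])["error_rate"].mean())
```

Output:

```
method    size
hbci      1       0.220625
          2       0.057292
          4       0.011280
majority  1       0.220625
          2       0.219792
          4       0.126190
Name: error_rate, dtype: float64
```

Single observers err on ~22% of trials. Plain-majority pairs are no better
(22.0%): when the two members disagree the coin flip wins only half the
time. hBCI-weighted pairs cut the error to 5.7% because the confidence
weight almost always sides with the correct member, and groups of four
reach 1.1%. The estimated weights separate correct from incorrect trials
cleanly (mean `w` of 0.95 vs 0.17 in this run).

The same entry points are available from the shell:

```bash
hbci simulate --participants 10 --seed 1 --out scratch/cohort
hbci evaluate --participants 10 --seed 1 --methods majority,hbci --out scratch/run
```

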