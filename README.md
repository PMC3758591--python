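# drowsetune

EEG-based drowsiness detection with a genetic-algorithm-weighted classifier
ensemble, plus a personalized refreshing-music recommender — the software
core of a system that watches a driver's single-channel EEG and, when
drowsiness appears, plays a piece of music the driver has previously found
refreshing.

It is written for researchers and engineers prototyping physiological
driver-monitoring pipelines who need a tested, reproducible reference
implementation that runs end to end on synthetic data.

## The model

**Features.** The raw trace (microvolts, 500 Hz) is cut into 1000-sample
windows. For each window the one-sided squared-magnitude DFT spectrum
`X(ω) = |FFT(x)|²` is summed over the four clinical bands
(δ 0.5–3 Hz, θ 4–7 Hz, α 8–13 Hz, β 14–30 Hz) to give band energies `E_b`,
which are normalized to relative energies

    RE_b = E_b / (E_δ + E_θ + E_α + E_β),      Σ_b RE_b = 1.

Classifier inputs are *patterns*: concatenations of `n` consecutive RE
vectors (4·n values), labelled by their last window.

**Base classifiers.** Three drowsy-probability estimators: a backprop
neural network with logistic units (hidden width = 2 × input, 3 hidden
layers), a soft-margin SVM (polynomial kernel by default) whose decision
value feeds the fixed sigmoid `P = 1/(1 + e^{−f(x)})`, and a kNN estimator
(`k = 3`) returning the drowsy fraction among the k Euclidean-nearest
reference patterns. The pattern lengths are 3, 3 and 4 windows
respectively.

**Integration.** The ensemble probability is
`LP = w₁P₁ + w₂P₂ + w₃P₃` with `Σwᵢ = 1, wᵢ ≥ 0`. The weights are found
by a binary genetic algorithm: 16 bits per weight, decoded as
`wᵢ = Dᵢ/2¹⁶` and renormalized; fitness `f(W) = 1/(dif + 1)` with

    dif = Σ_{drowsy patterns} (1 − LP) + Σ_{non-drowsy patterns} LP;

roulette selection, single-point crossover (p_c = 0.7), per-bit mutation
(p_m = 0.001), generational replacement with elitism.

**Music model.** Each MIDI melody is summarized by six features — average
pitch AP, pitch entropy PE, pitch density PD (= distinct pitches / 128),
average duration AD, duration entropy DE and pitch-interval entropy PIE
(all entropies in bits). A per-user binary decision tree is grown over
these features by gain-ratio splitting (cut candidates are adjacent-value
midpoints; the ratio divides the information gain by the post-split
entropy); each leaf stores the fraction of refreshing pieces that reached
it — the *refreshing score* in [0, 1]. Songs are scheduled with
probability proportional to their score, `P(s) = F(s)/Σ F(s′)`, so good
refreshers dominate without any song monopolizing playback.

## Worked example

```python
from drowsetune import (DrowsinessDetector, GaConfig, SessionPlan,
                        RefreshModel, gen_eeg, gen_user_table, song_catalog)

# 200-window synthetic drive, alternating drowsy/alert segments
plan = SessionPlan.alternating(8, 50.0)
signal, labels = gen_eeg(plan, seed=1)
res = DrowsinessDetector(signal, labels).fit(
    ga_config=GaConfig(population_size=50, generations=300, seed=1), seed=1)
print(res.summary())
```

prints

```
Drowsiness detector fit
=======================================================
windows: 200  (drowsy 100, alert 100)
pattern lengths (ann, svm, knn): (3, 3, 4)
decision threshold: 0.5

ensemble weights (GA):
  w1 (ann) = 0.0000
  w2 (svm) = 0.0000
  w3 (knn) = 1.0000
  best fitness = 1.000000

training-set performance (%):
  classifier    correct      FP      FN
  ann             100.0     0.0     0.0
  svm             100.0     0.0     0.0
  knn             100.0     0.0     0.0
  ensemble        100.0     0.0     0.0
```

All three classifiers separate this synthetic session perfectly (its
drowsy windows carry strong α/θ activity and its alert windows strong β,
with a wide margin), so the dif of any pure-classifier weighting is 0 and
the GA settles on one of the equivalent optima — here all weight on kNN
with the maximal fitness 1.0. `FP` is the share of alert windows flagged
drowsy (false alarms); `FN` the share of drowsy windows missed.

The music side:

```python
table = gen_user_table(40, rule=lambda r: r["F4"] <= 0.7, seed=0, ad_gap=(0.6, 0.8))
rm = RefreshModel(table).fit()
print(rm.summary())
catalog = song_catalog(10, seed=5, ad_gap=(0.6, 0.8))
print(rm.recommend(catalog, seed=7))
```

```
Refreshing-music model fit
========================================
records: 40
tree height: 2 (limit 25)
leaves: 2
training accuracy (score >= 0.5): 1.000
5
```

The planted rule "refreshing iff average duration ≤ 0.7 s" is recovered
as a single root split (tree height 2 = root + leaves), and the scheduler
recommends song 5 from the ten-song catalog.

The same pipeline is available from the shell:

```sh
drowsetune simulate --seed 1 --out eeg.csv --labels labels.csv
drowsetune train-detector --eeg eeg.csv --labels labels.csv --seed 1 --out model.json
drowsetune detect --eeg eeg.csv --model model.json --out decisions.csv
drowsetune evaluate --decisions decisions.csv --labels labels.csv
```

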