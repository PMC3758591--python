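# Methods

This note records the modelling choices behind `drowsetune`: what each
stage computes, which parameters matter, what the synthetic generators do
and do not emulate, and where the design was genuinely open.

## Spectral features

A window of `T = 1000` samples at `fs = 500` Hz (2 s) is transformed by a
real FFT; the power spectrum keeps bins `i = 1 .. T/2` (frequencies
`fs·i/T`, resolution 0.5 Hz). The DC bin is excluded: it carries the
electrode offset, not rhythmic activity, and the band definitions start at
0.5 Hz. Band energies sum the spectrum over closed intervals
δ [0.5, 3], θ [4, 7], α [8, 13], β [14, 30] Hz. Bins in the 3–4, 7–8 and
13–14 Hz gaps belong to **no** band — the bands are implemented exactly as
defined rather than extended to tile the axis, so a 3.5 Hz tone
contributes nothing to any band. Relative energies divide each band by
the four-band total; the β numerator uses `E_β` (the four ratios must sum
to one for the normalization to mean anything). Windows are
non-overlapping by default (`stride = T`): overlapping windows would make
consecutive training patterns nearly duplicate, which inflates apparent
accuracy without adding information; the stride is configurable for
streaming-style use.

Patterns concatenate `n` consecutive RE vectors and take the label of the
**last** window: the pattern describes the signal history ending at the
decision time, so the decision time's state is the natural target.

## Base classifiers

* **Neural network** — input `4n`, three hidden layers of `2·4n` logistic
  units, one logistic output; full-batch gradient descent on the
  mean-squared error against 0/1 targets, fixed learning rate 0.5 with
  classical momentum 0.9, at most 800 epochs, stopping early when the
  loss improvement falls below 1e-9. Xavier-style uniform initialization
  from a seeded generator makes training bit-reproducible. Width and
  depth follow the two-times-input convention; the optimizer details are
  our own (simplest scheme that trains this size reliably).
* **SVM** — scikit-learn's C-SVC does the quadratic programming; kernels
  linear / polynomial / rbf / sigmoid, polynomial of degree 3 (a common
  default; the degree is configurable) with `coef0 = 1` so lower-order
  terms participate. The drowsy probability is the **fixed** sigmoid
  `1/(1+e^{−f(x)})` of the decision value — no Platt-parameter fitting,
  the map is part of the model definition. Fitted machines serialize
  their support vectors and dual coefficients to JSON and are evaluated
  by an internal kernel routine, so a saved model needs no solver state.
* **kNN** — `k = 3` (odd, so the implied vote cannot tie), Euclidean
  distance, probability = drowsy fraction among the k nearest reference
  patterns. Distance ties at the k-th neighbour are broken by stable
  reference order, which makes results independent of the distance
  library's internal ordering.

Pattern lengths default to 3 windows for the ANN and SVM and 4 for kNN —
the lengths at which each classifier performs best. The ensemble keeps
three pattern views of the same window stream and aligns them on the
decision time, dropping the first `max(PL) − 1` windows where the longest
pattern is undefined (the warm-up).

## Genetic-algorithm weight search

The decoded raw weights `Dᵢ/2¹⁶` need not sum to one, but the integration
formula requires a convex combination; decoding therefore renormalizes,
which preserves the 16-bit resolution of the *direction* of the weight
vector while enforcing the constraint. The all-zero chromosome has no
direction and is invalid: it is redrawn at initialization and mutation.

Selection is fitness-proportional roulette — the simplest scheme
consistent with "selected by fitness". Crossover is single-point at a
uniform cut. Elitism (1 by default) re-inserts the best chromosome found
so far, making the best-fitness trace monotone. Because `dif` is linear
in the weights, the optimum over the simplex generically sits at a vertex
(all weight on the best classifier); mixed optima occur exactly when
classifiers tie. Defaults: population 50, `p_c = 0.7`, `p_m = 0.001`,
3000 generations; the library API accepts a reduced `bits_per_weight` so
the search can be validated against exhaustive enumeration of every
chromosome (2¹⁸ at 6 bits per weight), for which the per-bit mutation rate
is raised to `1/L` (the standard one-flip-per-chromosome heuristic for
short strings). The drowsy decision threshold on LP is 0.5 and
configurable; it is a deployment choice, not part of the fitted model.

## Music features

All entropies use base-2 logarithms (bits); any fixed base would only
rescale them. Duration entropy counts *rhythm classes*: durations are
binned on a 1 ms grid before counting, so floating tempo arithmetic
cannot split one nominal note value into two classes (at 120 bpm and 480
ticks per beat one tick is ≈1.04 ms, so the grid is at the tick scale).
Melody selection takes the non-percussion track with the highest mean
pitch — a common heuristic; an explicit track index overrides it. The
built-in MIDI codec covers note-on/off pairing (FIFO per channel+pitch,
velocity-0 note-ons treated as note-offs, running status honoured) and
the tempo map; controllers, SMPTE division and format-2 files are out of
scope. Chords within the melody track are kept as individual notes
ordered by onset; the feature definitions operate on the note list and do
not require monophony.

## Refreshing-music tree

Candidate cuts are midpoints of adjacent distinct sorted feature values.
The split score is `(H_before − H_after)/H_after` where `H_after` is the
**size-weighted child entropy** — weighting is required, otherwise a very
unbalanced split can show negative gain. Dividing by the post-split
entropy (rather than by the split information of textbook C4.5) is a
deliberate fidelity choice, kept as defined with an explicit convention:
pure children give `H_after = 0`, the ratio is +∞ and such a split beats
any impure one; remaining ties break by larger gain, then lower feature
index, then lower cut. Records equal to the cut go left (`≤ K`). Growth
stops on purity, at the height limit (default 25 levels, counting the
root; past that height precision no longer improves and the tree
overfits), when no cut has positive gain, or when a split would starve a
child below `min_leaf`. Leaves store `(refreshing, total)` counts and the
score is exactly their ratio.

Scheduling normalizes scores to probabilities; an all-zero score table
(nothing has ever refreshed the user) falls back to uniform so the system
keeps exploring. A re-played song's outcome overwrites its previous
label — the table is keyed by music id and reflects the latest evidence.

## Synthetic generators

`gen_eeg` renders each plan segment as one sinusoid per band plus white
noise. Amplitude ranges follow the classical physiology: drowsy segments
draw α from 30–50 μV and θ from 10–30 μV with β nearly absent (2–5 μV);
alert segments draw β from 15–60 μV with α suppressed to 5–15 μV; δ stays
at 5–15 μV in both states (drivers are not in deep sleep) and the noise
standard deviation is 2 μV. Windows spanning a state change take the
majority state as label. These traces make the two states linearly
separable in RE space by construction — which is the point: they validate
the pipeline's mechanics (spectral estimation, pattern bookkeeping,
training, integration, thresholds), **not** the clinical difficulty of
drowsiness detection. Real EEG carries broadband 1/f structure, blink and
muscle artifacts and gradual state transitions, none of which are
emulated; passing tests on this generator says the machinery is correct,
not that field accuracy would match.

`gen_notes` random-walks pitch (rounded Gaussian steps, reflected into
the pitch range) with uniform durations quantized to 1 ms.
`gen_user_table` labels generated songs by a planted predicate with
optional label-flip noise; the `ad_gap` option keeps a margin around a
duration threshold so a planted duration rule has no borderline songs.
`closed_loop_sim` replays the weekly protocol: drowsy events trigger a
pick from the current schedule, success is decided by a driver-response
predicate, outcomes accumulate in the table and the tree is rebuilt at
the end of each week; week one runs uniformly random for lack of data.
Precision is successful/total recommendations per week.

## Problem sizes and determinism

The test suite and acceptance script run on deliberately small instances
chosen to exercise every code path with comfortable statistical margins:
400-window EEG sessions (≈13 minutes of simulated signal), 10–40-pattern
GA contexts with exhaustive validation at 6 bits per weight, 30–40-song
catalogs, 100,000 scheduler draws, 20-seed closed-loop replicates. Every
stochastic component draws from `numpy.random.default_rng` with an
explicit seed; identical seeds give bit-identical signals, chromosomes,
melodies and schedules.

## Known limitations

* The synthetic EEG is far easier than real recordings; reported
  correctness on it is a mechanism check, not a clinical benchmark.
* The SVM probability map is a fixed sigmoid, so its probabilities are
  monotone in the margin but not calibrated.
* The gain-ratio denominator differs from textbook C4.5 split
  information; trees may prefer purer, smaller splits than C4.5 would.
* The MIDI codec is minimal by design (see above).
* The closed-loop simulator assumes a stationary driver-response rule;
  real preference drift would require forgetting, which the latest-label
  policy only crudely approximates.
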