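# Methods

## Model

The pipeline classifies multi-channel EEG segments from the per-timepoint
ordering of channel amplitudes alone. Its assumptions, in order of how
much they matter:

- **Orderings carry the class signal.** Everything downstream of the
  rank transform sees only which channels are larger than which at each
  instant. Amplitude units, offsets, and any strictly increasing
  rescaling of the signal are irrelevant by construction.
- **Transitions summarize dynamics.** The ChannelPat histogram counts
  ordered pairs of adjacent entries in the flat rank sequence. Pairs
  within a time point encode the instantaneous ordering; pairs that
  straddle two time points encode how the ordering hands over from the
  bottom of one instant to the top of the next. Both are counted; the
  histogram of a C-channel, N-sample segment always sums to C·N − 1.
- **Channel count is a free parameter.** C = 14 (the Emotiv Epoc X
  montage) is the default and fixes the sizes quoted throughout
  (196 = 14² features, the 10..196 selection range, the 288-symbol
  sentence for 144 selected features), but every stage is written for
  general C ≥ 2.

## Stage parameters

| Stage | Parameter | Default | Why |
|---|---|---|---|
| transform | tie rule | lower channel index first | stable sort; makes the transform deterministic and a constant column decode to 1..C |
| channelpat | block length | 2 | pairwise transitions; the C²-bin histogram is the feature vector |
| inca | NCA objective | softmax leave-one-out, L2 penalty λ = 1/n | the standard diagonal feature-weighting formulation; optimized with L-BFGS from w = 1, iteration cap 100 |
| inca | prefix range | 10..196 | 187 candidate sizes for C = 14 |
| inca | loss classifier | 1-NN, Euclidean, equal weights | minimal reading of "kNN with 10-fold CV"; k and metric are overridable |
| inca / tknn | z-scoring | per-feature, training-fold statistics | raw histogram counts are heavy-tailed; distances need comparable scales |
| tknn | grid | k 1..10 × {L1, L2} × {equal, inverse, squared-inverse} | 60 configurations |
| tknn | zero distances | exact matches get all the weight | inverse-distance weights diverge at d = 0; the majority label among exact matches wins |
| tknn | IMV ties | label of the most accurate contributing outcome, then smallest label | deterministic elementwise mode |
| tknn | folds | one stratified 10-fold split, shared by all 60 configs and reused nowhere else | outcomes must be comparable on the same samples |
| model | seeds | global seed fans out: INCA folds use `seed`, tkNN folds `seed + 1` | stages independently reproducible |

Entropies are in bits: a 4-symbol histogram is bounded by log₂4 = 2,
a 16-cell transition table by log₂16 = 4.

## Protocol bias, stated plainly

Two steps of the published protocol evaluate on the labels they
optimize against, and the implementation reproduces both deliberately
rather than silently "fixing" them:

- INCA picks the prefix size whose cross-validated accuracy is largest,
  after ranking features with an NCA fitted on the full labelled
  matrix. With many features and few samples this inflates the
  apparent accuracy even for random labels (the classic selection-bias
  effect): on a label-permuted 200-segment synthetic dataset with 196
  features, the in-protocol pipeline reports ≈ 0.82 where chance is
  0.50, while the classifier stage alone reports ≈ 0.57.
- The greedy tkNN winner is the maximum of 118 accuracies measured on
  the same labels.

The headline accuracy is therefore the protocol's internal figure. The
test suite guards against *implementation* leakage with two checks that
are immune to this optimism: the classifier stage alone must stay
within a union-Hoeffding band of the majority rate under permuted
labels, and a model selected in-protocol on one half of permuted data
must predict the held-out half at chance.

## Synthetic data

The generator emulates exactly one property of real recordings: a
class-dependent channel-amplitude *ordering*. Class A gives channels
ascending gains 1 + effect·(c−1)/(C−1), class B the reverse; each
sample is gain × |sinusoid| + Gaussian noise, with a per-segment random
frequency (4–12 cycles) and phase. Defaults: 14 channels, 256 samples,
40 segments per class, effect 0.8, noise sd 0.5 (the oscillation has
unit amplitude, so orderings are informative near its peaks and
noise-dominated near its zero crossings — the defaults give a separable
but imperfect problem).

What passing tests therefore show: the pipeline recovers planted
ordering structure, its accuracy rises with the planted effect, and it
finds nothing in permuted labels (held-out). What they do not show:
performance on real EEG, which has 1/f spectra, oscillatory bands,
artifacts, inter-subject variability and non-stationarity that the
generator deliberately omits.

Problem sizes in the test suite and the acceptance script (80–200
segments, 196 features, full 10..196 selection range, full 10-fold
protocol) were chosen so a complete run finishes in seconds on one CPU
while still exercising every structural count at its published size.

## Numerical choices

- NCA distances are exponentiated after subtracting the per-row
  minimum, so the softmax is overflow-safe; the reported weight is the
  square of the optimized parameter, hence nonnegative.
- Constant features are given unit scale during z-scoring rather than
  dividing by zero; an entirely constant matrix triggers a warning and
  degenerate (equal) weights.
- Accuracy ties across INCA sizes go to the smallest size (parsimony);
  ties across tkNN outcomes go to classifier-wise before voted, then
  lower index.
- Transition-matrix rows with no outgoing transitions stay all-zero
  instead of being renormalized.
- Metric cells with zero denominators are NaN ("undefined" in the text
  table), never silently 0. Overall rows are unweighted macro means;
  accuracy is the global fraction correct; the per-class geometric mean
  is √(sensitivity × specificity).

## Known limitations

- The rank transform ignores amplitude magnitude entirely; a class
  difference expressed purely in overall power is invisible.
- Diagonal NCA is O(n²p) per gradient step; a few hundred segments are
  comfortable, tens of thousands are not.
- The Lobish layer depends on the channel→lobe table; only the
  14-channel Emotiv table is built in, and its 8/2/2/2 lobe imbalance
  means frontal symbols dominate sentences for purely combinatorial
  reasons — compare against that baseline before reading meaning into
  an F-heavy sentence.
- EDF reading is a thin adapter (no filtering, re-referencing or
  resampling); segments are assumed artifact-free on arrival.
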