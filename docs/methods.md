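# Methods

## Selection criterion and candidate space

Feature selection is a filter: for each size constraint `s:t` (s sensors,
t time points, the same t time points shared by every chosen sensor) the
package enumerates all C(S, s)·C(T, t) candidate feature sets and keeps the
one maximising the estimated mutual information I(S; C) between the joint
feature vector and the chemical class.  Scoring the *joint* vector — rather
than pairwise feature–class terms — means redundancy between features about
the class is not double-counted and feature synergies contribute; this is
exactly why the search is exhaustive rather than greedy (a Battiti-style
incremental search would be cheaper but can miss synergistic sets; the
candidate spaces here are small enough that exhaustive evaluation costs
seconds per training split).

Ties are resolved deterministically: candidates within 1e-12 nats of the
maximum count as tied, the lexicographically smallest (sorted sensors, then
sorted time indices) wins, and the tie count is recorded on the result
rather than hidden.

## The nearest-neighbour MI estimator

`mi_knn_cd` handles the mixed continuous-feature / discrete-class pair with
the Kraskov–Stögbauer–Grassberger counting scheme under a 0/∞ metric on the
class: for each point i, d_i is the Chebyshev distance to its k-th nearest
neighbour among points of the *same* class, m_i counts pooled points within
d_i (self excluded), and

    Î = ψ(n) − ⟨ψ(n_ci)⟩ + ψ(k) − ⟨ψ(m_i)⟩   (nats).

Properties that motivated this form: it is exactly 0 when only one class is
present (m_i = k), unbiased-to-first-order under independence, and it
reduces to the usual KSG bias-corrected estimate of the density ratio
log p(x|c)/p(x) averaged over points.  It is validated against three
independent oracles rather than any particular historical toolkit: the
exact plug-in MI on discretised data, a numerically integrated two-Gaussian
benchmark, and the zero of independent data.

Numerical choices:

- `k = 4` by default.  Small k keeps bias low on 180-sample training folds;
  k is surfaced in `EstimatorSettings` and on the CLI.
- Chebyshev (max-norm) distances, the conventional KSG product-kernel
  geometry.
- Columns are standardised (own mean/sd) before estimation so sensors with
  large amplitudes (SnO2, ~0.9 peaks) do not dominate the metric over
  low-amplitude ones (CTO, ~0.2).
- Exact ties are broken by a uniform jitter of amplitude 1e-10·sd assigned
  in a canonical (sorted) row order with a seed derived from the matrix
  content hash plus the user seed.  Consequences: estimates are reproducible
  bit-for-bit, and permuting the samples permutes the jitter with them, so
  estimates are permutation-invariant bit-for-bit (the digamma averages are
  additionally summed in sorted order to fix the floating-point reduction
  order).
- Negative estimates are possible on independent data and are *not*
  clamped: selection compares estimates, and clamping would collapse the
  tie structure among near-zero candidates.
- Degenerate inputs: an all-constant matrix raises; a constant column is
  centred to 0, gets jitter only, and is logged.

During exhaustive selection the full 72-column training matrix is
standardised and jittered once and candidates are scored as column subsets
(both operations are column-wise, so this equals per-candidate
preprocessing up to the jitter draw).  Per-column pairwise |Δ| matrices are
cached and a candidate's Chebyshev matrix is their elementwise maximum,
which makes a (3,1)-constraint scan of 1320 candidates on a 180-sample
training fold take about a second.

`mi_plugin` is the exact maximum-likelihood MI of the empirical joint of
(feature-row tuple, class) for integer-valued features — the brute-force
oracle.  Its known upward bias on near-continuous data is why the
monotone-degradation property of the generator is checked with the kNN
estimator over the full noise range and with the plug-in only while the
noise is comparable to the bin width.

## The pointwise-MI classifier

`local_mi_scores` evaluates the per-point version of the same estimator,
i(x; c) = ψ(k) − ψ(m) + ψ(n) − ψ(n_c) with d taken to the k-th neighbour in
class c.  Its argmax over classes is the `mi_ml` classifier; since
exp i(x;c) estimates p(x|c)/p(x), the argmax is a maximum-likelihood rule,
equivalent to the posterior argmax under equiprobable priors (the study
design is class-balanced).  With `exclude_query=True` each query is assumed
to be a training row and its zero-distance self-match is excluded, which
makes the prior-weighted mean of own-class scores agree with the global
estimate up to O(1/n_c) digamma offsets — a tested link between the local
and global quantities.

## Classifiers

- `margin`: sklearn SVC adapter.  Cost series 1, 4, …, 65536 (nine values);
  the endpoint 65536 is the conventional reporting cost.  RBF γ by rule:
  1/n_features or the inverse 0.1/0.5/0.9 quantile of pairwise training
  distances.
- `knn`: Euclidean majority vote with k defaulting to the per-class
  training count (180/20 = 9) — the most any class can contribute to a
  neighbourhood; vote ties break to the tied class with the nearest single
  member.
- `bayes_net`: Gaussian networks with a variance floor of 1e-9.  `naive`
  treats features as conditionally independent given the class;
  `time_chain` (the reported modification) gives each feature the same
  sensor's previous selected time point as an extra parent with per-class
  linear-Gaussian conditionals, collapsing to `naive` when only one time
  point is selected.  A vector-node-per-time-point variant is not
  implemented; only the per-feature structure has reported results to
  anchor it.
- `mlp`: sklearn MLPClassifier adapter, one hidden layer of 12 units,
  L-BFGS (quasi-Newton), max 100 iterations, seeded.
- `mi_ml`: as above, k = 4.

All classifiers are deterministic given (data, spec, seed) and consume /
produce only `FeatureMatrix` / `PredictionSet`, so the adapters are
swappable.

## Protocol

`make_cv_splits` builds repeated balanced k-fold partitions: per
repetition, each class's samples are shuffled and dealt evenly into folds,
so every fold tests the same number of replicates of every chemical
(defaults 10 folds × 10 repetitions → 100 splits of 180/20 for the
200-sample study shape).  Class counts must be divisible by the fold count;
anything else raises rather than silently unbalancing folds.

Selection happens on training folds only — a mutation test asserts that
editing test rows cannot change a split's selection.  The random baseline
draws `n_random` (default 100) feature sets uniformly from the same
constrained candidate space and evaluates the j-th set on split
j mod n_splits, so both arms see identical partitions.

The significance test is t = (m1 − m2)/√((s1² + s2²)/n) with df = 2n − 2,
where the groups are **per-repetition mean accuracies** and n is the number
of repetitions (per-split accuracies within a repetition share training
data and are not independent; repetition means are closer to it).  Welch
df is available as an option.  If both groups have zero variance, p is 1
when the means agree and 0 otherwise.

## Synthetic data: what it emulates, what it does not

The generator emulates a two-chamber metal-oxide array measuring headspace
samples: per (sensor, class) peak amplitude A[s,c], a unit-peak
double-exponential kernel g_s(t) = (1 − e^(−t/τ_r))·e^(−t/τ_d) with
τ_r ∈ [20, 30] s and τ_d ∈ [120, 180] s per sensor (peak ≈ 40–60 s,
matching the observed response shape), sampled at 10–60 s in 10 s steps:

    r = A[s,c] · g_s(t) · (1 + η_mult) + η_add

with multiplicative noise (sd 0.05 per sample×sensor, emulating
replicate-to-replicate sensitivity variation) and additive noise (sd 0.01
per cell, baseline noise).  The kernel is normalised to unit peak so A is
literally the peak response; CTO amplitudes are drawn in [0.05, 0.25] and
SnO2 in [0.4, 1.0], reproducing the ~0.2 vs ~0.9 sensitivity contrast of
the two chemistries.  Informative sensors (default 1–3 and 7–9, three per
family) get an independent amplitude per class; non-informative sensors
respond identically to every class and hence carry exactly zero class
information at zero noise.  Everything is drawn deterministically from the
config seed.

`planted_best_feature_set` is the generator-side oracle: exact plug-in MI
on the noiseless class means discretised into 0.05-wide bins, brute-forced
over all candidates.  The coarse bins matter: they prevent a single
continuous-valued sensor from trivially separating all classes, so the
oracle ranks genuinely multi-sensor information.

Not emulated — and therefore not demonstrated by passing tests: sensor
drift over days, sample carry-over, concentration series, correlated noise
between sensors, and non-Gaussian noise tails.  Recovery and
MI-beats-random results on this generator show the machinery is correct,
not that any particular real array is classifiable.

## Problem sizes used in the shipped checks

The estimator benchmarks use n = 2000 samples (median over 20 seeds);
consistency is checked at n ∈ {250, 1000, 4000}.  Planted-pair recovery
runs 100 generator seeds at 10 classes × 10 replicates.  The
MI-vs-random evaluation runs the full 20×10 study at constraints 2:1 and
3:1 with 5 repetitions of ten-fold CV and 100 random sets per constraint —
sizes chosen so the whole suite runs in a few minutes while the t-test
retains 8 degrees of freedom.

## Known limitations

- The exhaustive search scales as C(S,s)·C(T,t) per split; it is intended
  for array-design problems (tens of sensors), not omics-scale feature
  counts, where greedy/mRMR-style approximations become necessary.
- The kNN estimator needs ≥ k + 2 samples per class in every training fold
  and degrades for very high-dimensional candidate sets (72 dimensions at
  180 samples is near the practical ceiling).
- The plug-in estimator is for integer-valued data only and is upward
  biased at small n; it is an oracle, not a selection default.
- `load_dataset` takes responses as-is: any baseline correction must happen
  upstream.
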