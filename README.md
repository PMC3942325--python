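# enosemi

Mutual-information filter feature selection for chemical sensor arrays
(electronic noses), with a full evaluation harness: exhaustive max-MI
subset search, five classifier families, repeated balanced
cross-validation, random-feature baselines and significance testing.

## The problem

An electronic nose pairs an array of partially selective metal-oxide gas
sensors with pattern recognition to identify volatile chemicals.  Each
sensor produces a response trace per sample; a handful of fixed time
points are extracted from each trace, so a measurement becomes a grid of
*virtual sensors* — (sensor, time point) features.  For a 12-sensor array
with 6 candidate time points that is 72 features, far more than needed,
and fewer sensors means cheaper devices.  The question is which subset of
features to keep.

Wrapper approaches answer it by exhaustively re-training a classifier on
every candidate subset — accurate but enormously expensive.  `enosemi`
implements the *filter* alternative: score candidate subsets once, by an
information measure, independently of any classifier.

## The method

For a feature subset S and chemical identity C, the selection criterion
is the mutual information

    S* = argmax_S I(S; C) = argmax_S [ H(C) − H(C|S) ]

maximised exhaustively over a constrained candidate space: choose `s`
sensors and `t` time points, with the same `t` time points shared by all
chosen sensors (written `s:t`), giving C(12,s)·C(6,t) candidates per
constraint.  Because the MI of the joint feature vector is used (not a sum
of pairwise terms as in mRMR-style heuristics), redundancy between
features about the class is not double-counted and synergies are captured.

I(S; C) is estimated without binning by a Kraskov-style k-nearest-
neighbour estimator adapted to a discrete class variable: with d_i the
Chebyshev distance from point i to its k-th nearest neighbour *within the
same class* and m_i the number of points in the pooled sample within d_i,

    Î = ψ(n) − ⟨ψ(n_ci)⟩ + ψ(k) − ⟨ψ(m_i)⟩        (nats; ψ = digamma)

An exact plug-in estimator for integer-valued data is included as an
oracle, and the per-point (pointwise) version of the same estimator,
i(x; c) = log p(x|c)/p(x), doubles as a maximum-likelihood classifier.

The evaluation protocol mirrors standard practice: repeated balanced
k-fold cross-validation (default 10×10-fold: 100 splits of 180 training /
20 test samples for a 20-chemical, 10-replicate study), selection done on
training folds only, and the selected features compared against 100
randomly drawn feature sets per constraint across five classifiers
(linear/RBF soft-margin, kNN with per-class k, Gaussian Bayes networks,
an MLP, and the pointwise-MI classifier), with a two-sample t-test on
per-repetition mean accuracies.

Because the original instrument data are not distributable, the package
ships a synthetic e-nose generator with planted informative sensors and
the two-family (CTO / SnO2) amplitude contrast, so every stage is testable
against known ground truth.

## Worked example

```python
import enosemi as en

# a 20-chemical, 10-replicate synthetic study; sensors 1-3 (CTO) and
# 7-9 (SnO2) are informative by construction
study = en.generate_enose_dataset(en.SyntheticConfig(seed=7))
ds = study.dataset

splits = en.make_cv_splits(ds.class_labels, n_folds=10, n_repeats=1, seed=0)
train = ds.subset(list(splits[0].train_indices))

sel = en.select_max_mi(train, en.SizeConstraint(2, 1), en.EstimatorSettings(seed=0))
print(sel.feature_set, round(sel.mi.value, 3), "nats")
```

prints

```
FeatureSet(sensors=(3, 7), time_indices=(5,)) 2.659 nats
```

i.e. under the two-sensors/one-time-point constraint the search picked one
informative sensor from each chemistry family, read at 50 s (near the
response peak), whose joint reading carries ≈2.7 nats of the maximum
ln 20 ≈ 3.0 nats of information about chemical identity.  The same
pipeline is available from the shell:

```
enosemi simulate --seed 7 --out data.csv
enosemi evaluate --data data.csv --constraint 2:1 --constraint 3:1 \
        --repeats 5 --out results/
enosemi report --evaluation-dir results/
```

which writes long-format accuracy tables, selection frequency and
family-composition tables, and MI-vs-random t-tests.

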