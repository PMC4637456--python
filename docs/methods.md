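# Methods

## Problem and model

The package assigns a protein sequence to one of four J-protein (HSP40)
types. The classifier is not a single model but a procedure: encode the
sequence as a fixed-length hybrid feature vector, optionally select a
subset of features by relevance to the class, rebalance the training
data, and vote over twenty heterogeneous subclassifiers. The sections
below record the exact definitions, the defaults and why they were
chosen, and the places where the design was genuinely open.

## Feature encoding

**SAAC (60 values).** The sequence is split into the N-terminal `lnc`
residues, the centre, and the C-terminal `lnc` residues; each segment
contributes its 20-letter amino-acid frequency vector (alphabetical
residue order). Default `lnc = 22` — the terminal length at which the
SAAC-only classifier peaks in the reference benchmark. Sequences
shorter than `2·lnc + 1` cannot form three nonempty disjoint segments;
training mode treats them as errors, prediction mode falls back to
three contiguous near-equal thirds (`short_sequence_policy="thirds"`),
preserving the three-part intent without overlap.

**PseAAC (12 × γ_max values).** For each of 12 physicochemical
properties and each lag γ = 1..`gamma_max` (default 8), the feature is
the lag-γ autocovariance of the property profile along the sequence,
normalised by `L − γ`, with the property mean taken over the whole
sequence. The property values are standard amino-acid indices
(hydrophobicity KYTJ820101, hydrophilicity HOPT810101, accessible
surface area CHOC760101, flexibility BHAR880101, net charge KLEP840101,
residue volume CHOC750101, polarity GRAR740102, heat capacity
HUTJ700101, isoelectric point ZIMJ680104, surface transfer free energy
BULH740101, van der Waals volume FAUJ880103, side-chain interaction
KRIW790101). Each column is z-standardised over the 20 amino acids
before use — the established convention — which makes the features
invariant to each index's arbitrary affine scale (property-tested).
Because no published value set accompanies the reference benchmark,
numeric equality with other implementations' PseAAC values is not
claimed; the accessions above are the provenance record.

**PSSM autocovariance (20 × λ_max values).** The L×20 PSI-BLAST
log-odds profile is first mapped elementwise through the logistic
sigmoid `1/(1+e^(−x))`, then each residue column contributes its lag-λ
autocovariances, λ = 1..`lambda_max` (default 5), with column means
taken on the normalised matrix. A sequence without a homology profile
receives the all-zero fallback matrix; sigmoid maps it to constant 0.5,
so its entire PSSM block is exactly zero rather than an arbitrary
imputation. PSSM files are accepted in the PSI-BLAST ASCII dialect;
columns are remapped from the file's A R N D C … order to alphabetical
order on read, so feature indices never depend on the dialect.

Feature ordering is frozen (SAAC N/centre/C with residues alphabetical;
PseAAC property-major, lags ascending; PSSM-AC column-major, lags
ascending), giving 60 + 96 + 100 = 256 dimensions at the defaults and
stable names (`saac.N.A`, `pseaac.p3.g2`, `pssm.C.l4`) so selected
index lists are portable across runs.

## Feature selection

Symmetric uncertainty requires discrete variables, so each numeric
feature is discretised with the Fayyad–Irani minimum-description-length
method: recursive binary splits on class-entropy gain, a split accepted
only when the gain exceeds the MDL coding cost; a feature with no
acceptable cut collapses into a single bin and scores SU = 0, which is
the desired behaviour for uninformative columns. An unsupervised
equal-frequency binning (10 bins) is available as a fallback
discretiser. All entropies are base-2; `SU = 2·IG/(H(f)+H(C))` is 0
under empirical independence and 1 under bijective association, and 0
is returned when both variables are constant.

Incremental feature selection walks prefixes of the SU-ranked list and
keeps the best-scoring prefix, preferring the smaller prefix on ties.
The faithful evaluator trains the full ensemble under cross-validation
for every prefix; because that costs hundreds of ensemble fits, the
CLI also offers a clearly labelled single-random-forest surrogate
evaluator and a `step` parameter for coarser sweeps. Ranking is
computed once on the full dataset (the benchmark protocol); a
leakage-safe variant — re-ranking inside each training fold — can be
assembled from the same primitives, and users estimating generalisation
error should prefer it, since whole-dataset ranking lets test-fold
labels influence the selected features.

## Imbalance handling and the ensemble

Training data are rebalanced in two moves:

- **SMOTE** expands the rarest class to `smote_target` rows (default
  60): each synthetic row is `x + u·(nn − x)` for a uniformly chosen
  original `x`, one of its `k = 5` nearest same-class neighbours `nn`
  (Euclidean), and `u ~ U[0,1]`. Originals are always retained; `k` is
  clipped (with a warning) when the class has fewer than `k + 1`
  members. Synthetic rows are convex combinations of real same-class
  pairs (property-tested to 1e-9).
- **Undersampling** randomly permutes the majority class and splits it
  into `n_subsets = 20` subparts whose sizes differ by at most one.
  Each subpart joined with *all* rows of every other class forms one
  subdataset, so the majority class is fully covered across the
  ensemble while each subclassifier sees a roughly balanced sample.

One subclassifier is trained per subdataset, cycling round-robin over
four learner families — RBF network, random forest, naive Bayes,
logistic regression — each wrapped one-versus-rest, so the default
ensemble holds five models of each family. The source description is
ambiguous between "20 subclassifiers total" and "4 learners × 20
subdatasets"; the 20-total reading was chosen because the surrounding
text consistently counts 20 subclassifiers. The RBF network is realised
as a standard-scaled Gaussian random-feature map (100 components)
followed by logistic regression — a kernel-feature network trained
discriminatively. All other hyperparameters are the scikit-learn
defaults, frozen by the package version pin rather than a side file.

Prediction is by majority vote. When two or more classes tie for the
top vote count, the sample is assigned to the tied class whose training
centroid (per-class mean feature vector of the *real* training rows,
SMOTE excluded) is nearest in Euclidean distance. The reference method
names "nearest distance" without a metric or reference point; centroids
among tied classes only are the simplest consistent reading.

**SMOTE scope.** The benchmark protocol expands the rarest class once,
*before* cross-validation fold assignment (`benchmark_pre_cv`).
This means synthetic rows, built by interpolating training points, can
land in test folds — an optimistic bias that largely explains perfect
rare-class sensitivity in that protocol (a no-signal dataset still
reaches AvgSn ≈ 0.46 under it). The alternative `train_fold_only`
confines expansion to each training fold and measures honest
generalisation (the same null dataset scores ≈ 0.28, i.e. chance).
Both modes are first-class; reports should name the mode used, and
chance-level sanity checks in the test suite use the leakage-safe mode.

## Evaluation

Metrics are one-versus-rest per class: `Sn = TP/(TP+FN)`,
`Sp = TN/(TN+FP)`, `Acc = ΣTP/N`, `AvgSn = mean(Sn)`. Cross-validation
is stratified per class (each class independently permuted and split
into near-equal parts; fold k tests on part k of every class). Pooled
metrics — all test-fold predictions scored once — are the default
because per-fold sensitivity of a 2-sample class takes only values in
{0, ½, 1}; the mean of per-fold AvgSn is also reported. A class absent
from the truth vector has undefined sensitivity and is excluded from
AvgSn with a warning. Display rounding is half-up to 3 decimals.

## Synthetic benchmark

The generator emulates the structure of the curated benchmark: class
counts 63/55/1061/20, lengths uniform on [70, 300], per-class letter
distributions `(1−b)·uniform + b·q_c` with `q_c ~ Dirichlet(2·1)` and
`b = composition_bias` (default 0.3 — separable but far from trivial;
`b = 0` is an exact no-signal null), optional planted N-terminal
motifs, and per-sequence integer PSSMs in [−6, 8] whose column means
carry a class-dependent shift of magnitude `pssm_signal` (default 2.0).
`composition_bias` is deliberately a mixing weight rather than a raw
Dirichlet concentration: a concentration alone cannot express "zero
bias ⇒ identical class distributions". Everything is deterministic
under the seed; regeneration is byte-identical (tested). What the
generator does *not* emulate: homology structure, domain architecture,
real HPD motifs, or length–class correlation. Passing tests therefore
demonstrate that the machinery behaves correctly in the intended
imbalance regime, not that the reported real-data accuracies transfer.

Behavioural tests run at the generator's full default size (1199
sequences, 10-fold CV, all pipeline defaults); one ensemble
cross-validation takes well under a minute. Scaling the counts down is
supported (`--scale`, floor of 2 per class) but distorts the regime:
the default SMOTE target of 60 is sized for full-scale minority counts
and would dominate shrunken classes.

## Numerical choices and edge cases

- Entropies: base-2 throughout; empty cells contribute 0.
- SU sort is stable with ties broken by original feature index; IFS
  ties prefer the smaller prefix.
- Homopolymer/constant profiles give autocovariances that vanish only
  to ~1e-30 (one ulp of the column mean), not exactly 0.
- Majority partition uses `np.array_split` after a seeded permutation:
  sizes differ by ≤ 1, larger groups first.
- All randomness flows from explicit integer seeds (`random_state` /
  `seed` parameters); per-fold and per-subclassifier seeds are derived
  by fixed offsets, so runs are reproducible bit-for-bit.

## Known limitations

- The per-property index values are a documented choice, not a
  published constant of the reference benchmark; other value sets give
  different PseAAC numerics (the pipeline's behaviour is insensitive to
  affine rescaling but not to choosing different indices).
- The pre-CV SMOTE protocol inflates rare-class sensitivity (see SMOTE
  scope above); honest error estimation needs `train_fold_only`, at the
  cost of protocol fidelity.
- Whole-dataset SU ranking before CV leaks label information into
  feature selection; the IFS optimum measured this way is optimistic.
- The ensemble trades majority-class sensitivity for minority coverage
  by construction; applications that penalise majority-class misses
  should weigh that trade-off.
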