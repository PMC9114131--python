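# Methods

## Problem

Given a training set of molecular graphs with scalar property labels
that was *selectively sampled* from a chemical space, and an unlabeled
uniform sample of that space, learn a regressor `f : graph → ℝ` whose
mean absolute error (MAE) on the uniform distribution is small. The
training and test inputs differ in distribution (covariate shift) while
the structure→property relation is shared.

## Graph model and network

A molecule is a connected undirected graph with typed nodes (atoms) and
typed edges (bonds: single / double / triple / aromatic), stored once
per edge with `u < v`. Atom types are one-hot encoded and linearly
embedded to `D` dimensions. One message-passing round computes, for
every node `v`,

    m_v = ReLU( Σ_{u ∈ N(v)} W_{σ(u,v)} h_u ),     h_v ← GRU(m_v, h_v)

where `W_b` is a `D×D` matrix per bond type `b`, shared across rounds,
and each undirected bond contributes in both directions. After `T`
rounds a set2set readout — an LSTM-driven attention recurrence over the
node states, invariant to node order — produces a `2D` graph vector,
followed by two linear layers. Heads: a scalar for regression, a
logistic probability for binary classification, or raw features.

Defaults follow the common protocol for this architecture: `T = 3`,
`D = 32`, Adam without weight decay, initial learning rate 1e-5,
reduce-on-plateau scheduling (factor 0.7, patience 5 epochs, monitored
on a held-out 20% validation split), batch size 64, and the checkpoint
with the lowest validation loss is returned. Regression targets are
standardized internally with training-set statistics. At the benchmark
scale used here (hundreds of training molecules) those defaults are far
too conservative to converge in reasonable time, so the packaged smoke
configuration uses `T = 2`, `D = 16`, two set2set steps, learning rate
5e-3, and at most 100 epochs with early stop when the learning rate
falls below 3e-6 — sizes chosen so one full three-method, ten-trial
comparison finishes in a few minutes on one CPU.

## Biased-sampling simulator

Four scenarios choose an indicator per molecule: (1) atom count,
smaller preferred; (2) fraction of non-single bonds, larger preferred;
(3) an auxiliary "gap"-like property, larger preferred; (4) the target
itself, larger preferred. A trial:

1. hold out a uniformly random 10% of the dataset as the unbiased test
   set (`round(0.1 · n)` molecules exactly);
2. min-max normalize the indicator on the remaining pool;
3. set the sigmoid pivot at the pool quantile of level `rate/2` toward
   the preferred end, and find by log-space bisection the gain for which
   the mean of `σ(gain · (pivot − x̃))` (smaller-preferred; mirrored
   otherwise) equals the target rate (default 10%) to 1e-5 — the mean
   is 0.5 at zero gain and drops below the rate as gain → ∞, so a root
   exists whenever the rate is achievable, and the min-max normalization
   makes the tuned gain invariant to affine rescaling of the indicator;
4. include each pool molecule in the training set by one independent
   Bernoulli draw at its inclusion probability (sampling without
   replacement: a molecule is drawn at most once and can never appear
   in both sets);
5. repeat with seeds `base + k`, 30 trials by default (10 in the smoke
   configuration).

The gain is tuned per trial on the post-test pool. Zero-bond graphs get
Scenario-2 indicator 0 (all-single convention). Scenario 3 requires an
auxiliary column and is refused on datasets lacking one.

## Synthetic population

`generate_population` draws graph sizes uniformly on 3–27 atoms, builds
a uniform random spanning tree (Prüfer sequence) for connectivity, adds
independent extra edges with probability 0.05 per non-tree pair, and
samples atom types (C/N/O/F, probabilities 0.6/0.15/0.15/0.1) and bond
types (0.7/0.15/0.05/0.1) i.i.d. Properties are linear combinations of
graph functionals (`n_atoms`, `frac_nonsingle`, `mean_degree`,
`count_type_<code>`) plus Gaussian noise; structure and noise use
separate RNG streams so property re-specification never changes the
graphs.

The packaged benchmark (3,000 molecules, seed-reproducible) carries
four columns: `target_size_linked` (4·mean_degree + 0.25·n_atoms,
noise sd 0.3), `target_bond_linked` (5·frac_nonsingle + 0.5·mean_degree,
sd 0.3), `gap_like` (2·mean_degree − frac_nonsingle, sd 0.2; used only
as Scenario 3's indicator), and `target_self` (2·mean_degree +
2·frac_nonsingle, sd 0.3). Targets deliberately lean on `mean_degree`:
under the spanning-tree-plus-extra-edges law it is monotone in graph
size (≈ 2 − 2/n plus an extra-edge term growing with n), so it is
strongly correlated with the Scenario-1 indicator *and* expressible
through an attention-based readout, whereas a raw atom count cannot be
recovered by a readout that averages node states. This keeps the
covariate-shift penalty real (the biased model is wrong precisely on
large molecules) while keeping the task learnable at desk scale.

What the generator does **not** emulate: chemical valence rules, 3D
geometry, realistic property distributions, or label noise that depends
on the molecule. Passing tests therefore demonstrate that the
corrections counteract the *simulated* selection mechanisms, not that
they improve any particular laboratory dataset.

## IPS

The propensity classifier sees graphs only — never property values —
labeled 1 for biased-training membership and 0 for test membership,
trained with cross-entropy; validation is a stratified 20% of both
sets, and the best-validation checkpoint scores every training
molecule. Scores are clipped to a floor of ε = 0.01 (config-exposed)
before inversion, the standard guard against exploding weights; class
imbalance is left uncorrected since only relative weights matter under
a fixed design. The regressor then minimizes the 1/π̂-weighted squared
loss. Note on normalization: the printed objective divides by the
realized training-set size N, whose expectation is the pool size times
the mean inclusion rate; the Horvitz–Thompson form (divide the weighted
sum by the pool size) is the estimator that is exactly unbiased for the
population mean loss, and the unbiasedness test uses that form.

## CFR

The feature extractor is the MPNN trunk without readout; the label and
weight heads each own a set2set readout. The IPM path mean-pools node
states to graph embeddings (cheap and order-invariant) and measures the
distance between the domain-split embedding clouds with entropic
optimal transport (Sinkhorn, uniform marginals, Euclidean ground cost,
regularization 0.05, 200 iterations); the transport plan is treated as
constant and the gradient flows through the cost matrix — the
envelope-theorem gradient of entropic OT in the ground costs. An exact
linear-program mode (scipy HiGHS) exists for testing. Importance
weights use the closed form `w = 1 + exp(φ^(0) − φ^(1))` with the
domain fixed to 1, computed from the weight head's scores without
gradient flow. Each mini-batch holds equal halves of training and
(cycled) test molecules; step A updates trunk + label head on
`o_property + α · o_IPM` with the weight head frozen, step B updates
the weight head alone on the domain cross-entropy, computed on detached
features so no domain gradient reaches the trunk.

Model selection uses plain (unweighted) MSE on a held-out 20% of the
training set: the importance-weighted objective changes meaning as the
weight head trains, so weighted validation losses from different epochs
are not comparable; unweighted MSE makes checkpoint selection
stationary.

α trades regression fit against distributional balance. At full scale
α = 10 is a customary choice; at this benchmark's embedding scale the
initial Wasserstein term is ~15% of the initial property loss, so
α = 10 makes the balance term dominate and the trunk collapses to
near-constant embeddings (observable as the IPM → 0 while the property
loss pins at the target variance and the domain loss at ln 2). The
smoke configuration therefore uses α = 0.1, sized so α·o_IPM starts at
roughly a tenth of o_property; α remains a config field.

## Evaluation

Per trial, MAE on the unbiased test set. Across trials, mean ± sd, a
two-sided paired t-test of each correction against the baseline
(pairing by trial seed), and star annotation (`**` p < 0.01, `*`
p < 0.05; all-zero differences report p = 1). Diagnostics: MAE in
equal-width bins of the scenario indicator (empty bins reported as
missing; count-weighted recombination reproduces the global MAE
exactly) and trial-averaged normalized train/test indicator histograms
on a common grid. Reports are JSON validated against the schema in
`src/molbias/schemas/report.schema.json`; trial results are
checkpointed so long runs can resume, and reruns of an identical
configuration produce byte-identical reports.

## Degenerate inputs and tie-breaks

Constant indicator vectors are rejected (normalization undefined); an
unachievable target rate raises with the achievable range; an empty
biased draw raises with the seed rather than silently resampling; a
constant-output propensity classifier is flagged as degenerate in the
report, not raised; non-finite losses abort training with diagnostics.
All randomness flows from explicit integer seeds (trial k uses
`base_seed + k`); forward passes are deterministic.

## Known limitations

The smoke-scale network under-fits relative to a full-scale run, so
absolute MAEs are not comparable to published benchmark values; only
the baseline/IPS/CFR ordering and its significance are meaningful here.
Weighted-loss training inherits the variance of extreme weights
(mitigated only by the clipping floor). The Sinkhorn gradient ignores
the plan's dependence on the costs, which is exact only at the entropic
optimum. CFR stability is sensitive to α, mirroring the known
transferability–discriminability trade-off of balanced representations.
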