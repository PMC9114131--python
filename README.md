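# molbias

Experimental molecular datasets are rarely uniform samples of chemical
space: researchers preferentially measure small, stable, synthesizable,
or fashionable compounds. A property regressor trained on such data
overfits the biased distribution and degrades exactly where it is most
needed — on the molecules nobody has measured yet. `molbias` implements
and evaluates two causal-inference corrections for this *sample
selection bias* on top of a message-passing graph neural network (MPNN):

* **IPS (inverse propensity scoring).** A graph classifier is trained to
  separate the biased training molecules (label 1) from an unbiased
  reference sample (label 0); its predicted membership probability
  π̂(G) is the propensity score. The regressor then minimizes
  `o_IPS = (1/N) Σ_i ℓ(y_i, f(G_i)) / π̂(G_i)` with squared loss ℓ,
  which is unbiased for the population loss when π̂ is correct.
* **CFR (counterfactual regression).** A single network with a shared
  feature extractor `f_F`, a label predictor `f_L` trained only on the
  labeled (biased) domain, a Wasserstein distance between the train- and
  test-domain embedding distributions penalized with weight α, and a
  domain-score head `f_W` whose softmax yields closed-form importance
  weights `w = 1 + exp(φ^(1−d) − φ^(d))`. Training alternates between
  (a) minimizing `o_property + α · o_IPM` over `f_F, f_L` with `f_W`
  frozen and (b) minimizing the domain cross-entropy over `f_W` alone.

Because no public dataset comes with ground-truth selection bias, the
package ships a biased-sampling simulator: four scenarios prefer
molecules with fewer atoms (1), fewer single bonds (2), higher values of
an auxiliary stability-like "gap" property (3), or higher target values
(4). Each molecule's inclusion probability is a sigmoid of its
normalized indicator whose gain is tuned by bisection so the average
inclusion rate is 10%; an unbiased 10% test set is held out first, and
the whole procedure is repeated over seeded trials for paired
significance testing on test-set MAE.

A synthetic molecular-graph generator (random spanning trees plus
Bernoulli extra edges, typed atoms and bonds, properties defined as
graph functionals plus Gaussian noise) makes everything runnable
without downloads; a SMILES-CSV loader (RDKit) covers real datasets.

All neural-network machinery — reverse-mode autodiff, the
edge-conditioned MPNN with GRU updates and set2set readout, Adam,
Sinkhorn and exact-LP optimal transport — is implemented in numpy
inside the package.

## Worked example

```python
from molbias import ScenarioConfig
from molbias.experiments import run_experiment, smoke_config

report = run_experiment(smoke_config(output_dir="runs/s1"))
for method, entry in report.summary.items():
    print(method, round(entry["mean"], 3), "+/-", round(entry["std"], 3),
          entry.get("stars", ""))
```

On the packaged Scenario-1 benchmark (3,000 synthetic molecules, a
size-linked target, 10 trials, small MPNN) this prints:

```
baseline 1.831 +/- 0.306
ips 1.732 +/- 0.284 *
cfr 1.735 +/- 0.347 *
```

i.e. both corrections lower test MAE relative to the uncorrected
regressor, with paired-t significance (`*` = p < 0.05, `**` = p < 0.01);
the mean propensity-classifier accuracy across trials is about 78%, and
the per-bin diagnostics in the report show the improvement concentrated
on large molecules — the region under-represented in the biased
training sets. The same pipeline is available from the shell:

```sh
molbias synth --n 3000 --seed 0 --out bench.jsonl
molbias sample --dataset bench.jsonl --scenario 1 --n-trials 10 --seed 0 --out splits/
molbias run config.yaml --out runs/s1
molbias report runs/s1
```

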