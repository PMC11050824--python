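# lsirm — latent space item response modeling

`lsirm` analyzes binary assessment data (ability tests, diagnostic
instruments, questionnaires scored right/wrong) for **conditional
dependence**: person-item interaction structure that the Rasch model's
main effects cannot express.  It augments the Rasch model with an
interaction map — persons and items both get positions in a shared
K-dimensional metric space, and the log-odds of a correct response is

    logit P(Y_pi = 1) = theta_p + b_i − lambda · d(xi_p, zeta_i)

with ability theta_p, item easiness b_i, positions xi_p and zeta_i,
Euclidean distance d, and a nonnegative distance weight lambda.  A larger
person-item distance lowers accuracy beyond what ability and easiness
predict.  A spike-and-slab prior on log lambda lets the data decide
whether any distance effect is warranted: the posterior slab probability
P(delta = 1 | Y) is the evidence for conditional dependence, and when it
is low the model collapses to plain Rasch.

Estimation is Bayesian (blocked adaptive MCMC, 3 × 1500 iterations by
default), followed by Procrustes alignment of the position draws —
translation, rotation and reflection are removed against the
highest-posterior draw, preserving all distances — to produce point
estimates of the map.  On top of the fitted map the package computes the
applied quantities: item distance matrices and item clusters, cluster
centers and inter-cluster distances, person-to-cluster distances with
farthest-cluster assignment, perceived-difficulty intervals
(b_i − lambda·d across persons), covariate overlays, and personalized
feedback reports.

Intended users: psychometricians and methodologists studying local item
dependence, test developers screening for unmodeled dimensionality, and
anyone generating person-level diagnostic feedback from assessment data.

## Worked example

Simulate a 200 × 20 test with a true distance effect (gamma = 2, item
positions in three blobs), fit, and inspect:

```python
import numpy as np
from lsirm import (
    GeneratorConfig, ModelConfig, RunConfig, simulate_lsirm, fit_lsirm,
    align_posterior, slab_probability, convergence_summary,
)
from lsirm.analytics import cluster_items, item_distance_matrix

data = simulate_lsirm(GeneratorConfig(n_persons=200, n_items=20,
                                      regime="lsirm", gamma=2.0, seed=42))
samples = fit_lsirm(data.responses, ModelConfig(), RunConfig(seed=42))

print("P(slab | Y):", round(slab_probability(samples), 3))
print("lambda_hat:", round(float(np.exp(samples.pooled("log_lambda")).mean()), 3))
print("max R-hat:", round(float(convergence_summary(samples).rhat.max()), 3))

aligned = align_posterior(samples)
labels = cluster_items(item_distance_matrix(aligned.zeta_mean), 3)
```

Output:

```
P(slab | Y): 1.0
lambda_hat: 2.131
max R-hat: 1.077
```

The slab probability of 1.0 is decisive evidence for conditional
dependence (the data were generated with one), lambda is recovered near
its true value 2, and all chains converge below the 1.1 cutoff.  The
recovered three-group item partition matches the generating blobs
exactly (adjusted Rand index 1.0), and the cluster table prints the
centers and inter-cluster distances:

```
         center_dim1  center_dim2  d_to_0  d_to_1  d_to_2  mean_distance
cluster
0              1.572        0.839   0.000   2.925   2.535          2.730
1             -1.353        0.857   2.925   0.000   2.650          2.788
2              0.199       -1.291   2.535   2.650   0.000          2.592
```

On Rasch-generated data the same fit drives P(slab | Y) toward 0,
reporting that no interaction map is needed.

## Command line

The same pipeline as a CLI:

```sh
lsirm simulate --regime lsirm --persons 200 --items 20 --seed 42 --outdir sim/
lsirm fit --responses sim/responses.csv --seed 42 --outdir fit/
lsirm report --fit-dir fit/ --responses sim/responses.csv --n-clusters 3 --outdir report/
```

`fit` writes posterior draws, aligned positions, a convergence report and
a run manifest; `report` writes every analytics table (distance matrices,
cluster table, person-cluster distances, perceived difficulty) as CSV.
Response CSVs can be wide (one column per item, empty cell = missing) or
long (`person,item,response`).

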