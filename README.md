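# grmec

Graph-regularized multi-view ensemble clustering for single-cell
multi-omics data.

Single-cell multi-omics protocols (CITE-seq, SNARE-seq, 10x Multiome, …)
measure several modalities — transcriptome, surface proteins, chromatin
accessibility — in the same cells. No single clustering method performs
well across all of these data types, and each modality alone is noisy.
`grmec` addresses both problems at once: it integrates the views through
a weighted joint nonnegative matrix factorization *and* integrates an
ensemble of base clustering results through a consensus co-cluster
affinity, coupling the two with graph regularizers so that they guide a
common soft cluster assignment.

Given views X¹…Xᵐ (cells × features, nonnegative) and a q × m grid of
base clustering results transformed into binary co-cluster indicators
Sʳᵛ, the model minimizes

```
  Σ_v w_v ‖Xᵛ − W Vᵛ‖²_F  +  λ₁ tr(Wᵀ L_H W)
+ Σ_rv α_rv ‖S − Sʳᵛ‖²_F  +  λ₂ tr(Hᵀ L_S H)
```

over nonnegative W (consensus cell representation, n × k), Vᵛ (per-view
bases), S (consensus affinity, n × n) and H (cluster indicator, n × C,
unit row sums), where L_H is the graph Laplacian of H Hᵀ and L_S that of
S. The view weights w_v = 1/(2‖Xᵛ − W Vᵛ‖_F) and ensemble weights
α_rv = 1/(2‖S − Sʳᵛ‖_F) are self-tuned, so unreliable views and poor base
results are down-weighted automatically. Optimization is by alternating
multiplicative updates (objective monotone non-increasing, all factors
stay nonnegative); hard labels are the row argmax of H. See
`docs/methods.md` for the full account, including why initialization
matters for this model class.

## Worked example

```python
from grmec import GRMECSC
from grmec.io import MultiOmicsDataset
from grmec.preprocess import normalize
from grmec.simulate import SimConfig, simulate_multiomics, simulate_base_set
from grmec.evaluate import adjusted_rand_index, normalized_mutual_information

# two omics views of 300 cells with a planted 4-cluster structure,
# plus a 3 x 2 grid of base clusterings corrupted at 10% label error
sim = simulate_multiomics(SimConfig(n=300, C=4, m=2, p=(500, 200), seed=0))
views = MultiOmicsDataset([normalize(v) for v in sim.dataset.views])
base = simulate_base_set(sim.truth, q=3, m=2, error_rates=0.1, seed=1)

model = GRMECSC(n_clusters=4, n_components=20, random_state=0).fit(views, base=base)
pred = model.predict_labels()
print("ARI vs planted truth:", round(adjusted_rand_index(sim.truth, pred), 3))
print("NMI vs planted truth:", round(normalized_mutual_information(sim.truth, pred), 3))
print("sweeps:", model.n_iter_)
```

prints

```
ARI vs planted truth: 0.991
NMI vs planted truth: 0.987
sweeps: 56
```

meaning the fitted hard labels agree with the planted partition almost
perfectly (ARI/NMI of 1.0 would be exact agreement up to relabeling) —
the consensus over six noisy base results plus the data term denoise the
10% label corruption — and the objective converged in 56 sweeps. The
fitted estimator also exposes `W_` (cell embedding), `S_` (consensus
affinity), `H_` (soft memberships), `view_weights_` and
`ensemble_weights_`.

The same flow is available from the shell:

```bash
grmec simulate --n 300 -C 4 --views 2 --p 500,200 --seed 7 -o sim/
grmec pipeline sim/manifest.yaml -C 4 -k 20 --seed 7 -o run/
cat run/metrics.json
```

which preprocesses each view (cell filtering, library-size + log1p
normalization, top-1000 highly-variable-feature selection), runs the
built-in base clusterers on every view, fits the model and writes
labels, a checkpoint and ARI/NMI against the simulation truth.
`grmec markers` ranks per-cluster marker features with one-vs-rest
Wilcoxon rank-sum tests.

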