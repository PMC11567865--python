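# peptinet

Multilayer signed partial-correlation network analysis for targeted
proteomics and neuropathology.

## The problem

Post mortem cohort studies of Alzheimer's disease increasingly measure
many molecular and cellular quantities on the same brains: targeted
mass-spectrometry abundances of synaptic (SNARE-interactome) peptides,
SNARE protein–protein interaction assays, amyloid and phosphorylated-tau
peptides, and immunohistochemical densities of plaques and tangles —
alongside ante mortem phenotypes such as wrist-actigraphy physical
activity and global cognition.  The scientific questions are relational:
which variables are *conditionally* dependent once everything else is held
fixed, how are those dependencies organized into modules and layers, do
they differ between more- and less-active people, and do specific
synaptic modules moderate the path from p-tau to tangle pathology?

`peptinet` implements that full analysis as a tested, reusable pipeline:

- **Estimation** — nonparanormal (rank-Gaussianizing) transform,
  pairwise-complete correlation with PSD repair, graphical lasso over a
  λ path solved by warm-started ADMM, EBIC (γ = 0.5) model selection, and
  conversion to the signed partial-correlation network
  w_ij = −Θ_ij/√(Θ_ii Θ_jj).
- **Topology** — strength, closeness, betweenness and expected influence
  on 1/|w| path lengths; hub detection (betweenness > mean + 2 SD); global
  and inter-layer connectivity; diameter; a continuous power-law fit with
  KS bootstrap for scale-free assessment.
- **Modules** — signed spinglass community detection (Reichardt–Bornholdt
  Hamiltonian with negative-edge handling, via igraph), Gómez signed
  modularity, transitivity, structural equivalence, module-by-annotation
  ANOVA.
- **Balance** — signed triangle census: a triangle is balanced iff the
  product of its edge signs is positive; global balance is the balanced
  fraction, and unbalanced motifs are listed for inspection.
- **Group comparison** — median split by activity, then a permutation
  test that reshuffles group labels and re-runs the *entire* estimation
  pipeline per permutation; Holm–Bonferroni over edge and centrality
  families.
- **Network-informed regressions** — module–cognition association
  adjusted for age/sex/education, and the three-way moderation of tangle
  burden by p-tau × synaptic-module level × physical activity (centered
  products, OLS).
- **Synthetic data** — a generator that plants all of the above (sparse
  signed precision structure with exact designed partial correlations,
  modules, a hub, a group-specific negative edge, non-normal marginals,
  missingness, phenotype effects) so every stage is testable against
  ground truth.  The cohort data this design mirrors are access-controlled,
  so the generator is a first-class component, not a fixture.

See `docs/methods.md` for the model, conventions, and design decisions.

## Worked example

```python
from peptinet.simulate import SyntheticConfig, generate_study
from peptinet.preprocess import nonparanormal_transform
from peptinet.ggm import estimate_network
from peptinet import topology
from peptinet.balance import global_balance
import pandas as pd

high, low, truth = generate_study(SyntheticConfig(seed=1))
X = pd.concat([high.X, low.X], ignore_index=True)   # 440 x 71
net, fit = estimate_network(nonparanormal_transform(X), truth.node_meta)

print(f"selected lambda = {fit.selected_lambda:.3f}")
print(f"edges = {len(__import__('peptinet').edge_list(net))}")
print(f"global connectivity = {topology.global_connectivity(net):.2f}")
bal = global_balance(net)
print(f"balance = {bal.n_balanced}/{bal.n_triangles}")
```

prints

```
selected lambda = 0.152
edges = 119
global connectivity = 16.62
balance = 43/43
```

i.e. the EBIC-selected multilayer network keeps 119 conditional-dependence
edges whose absolute weights sum to 16.6, and every closed signed triangle
in it is balanced (an all-positive or one-positive/two-negative sign
pattern), indicating a structurally stable configuration.

The same analysis is available from the shell:

```sh
peptinet run --seed 1 --out artifacts/        # simulate-then-analyze, all stages
peptinet report artifacts/                    # plots + markdown report
peptinet compare --data data.csv --covariates cov.csv \
    --node-meta meta.tsv --n-perm 10000 --seed 1 --out cmp/
```

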