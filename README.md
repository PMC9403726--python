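# neoconn

Graph-theoretical analysis of neonatal structural connectomes and their
association with behavioural outcomes in toddlerhood.

## The problem

Infants with congenital heart disease (CHD) are at elevated risk of
internalizing (anxious/withdrawn) and externalizing (inattentive/
aggressive) behaviour problems in early childhood. One candidate
antecedent is the organisation of the structural brain network — the
*connectome* — already measurable from diffusion MRI in the neonatal
period, before cardiac surgery. `neoconn` implements the full statistical
pipeline for this kind of study: it starts from per-subject weighted
adjacency matrices (e.g. 93 AAL-style parcellation regions × SIFT2
streamline-weight edges), and relates network features to behaviour
scores while adjusting for clinical and demographic covariates.

Because cohort datasets of this kind are rarely shareable, the package
ships a first-class synthetic-cohort generator that reproduces the data
structure of such a study — block-structured connectomes with
core–periphery organisation, realistic covariates, overdispersed
behaviour counts with an age trend, and an optional *planted* linear
edge-weight–behaviour effect — so every stage of the pipeline can be
validated end to end against known ground truth.

## What it computes

**Cost-corrected graph metrics.** Density, nodal strength/degree, global
efficiency `E_glob = ⟨1/d(i,j)⟩` (shortest paths under edge length
`1/w`), and nodal/local efficiency (efficiency of each node's
neighbourhood subgraph). To remove between-subject density confounds,
each metric is recomputed on proportionally thresholded networks over a
density grid (0.05–0.50 in 0.01 steps) and averaged ("cost correction").

**Core–periphery decomposition.** A Kernighan–Lin-style local search
(single-node flips with tabu sweeps, random restarts) maximising the
Borgatti–Everett correlation between the weight matrix and the ideal
core–periphery pattern. Edges are typed **core** (both endpoints core),
**feeder** (mixed), or **peripheral**.

**Network-based statistics (NBS).** A mass-univariate OLS fit at every
edge (`weight ~ intercept + behaviour + covariates`), thresholding of the
predictor t-statistics (default `t = 3.1`), extraction of connected
supra-threshold components, and family-wise error control of component
*extent* via Freedman–Lane permutation (default 10,000 permutations,
critical p = 0.025), plus a sensitivity sweep of the primary threshold
over t = 2.5–3.5.

**Behaviour statistics.** Age-residualized standardized scores, partial
Spearman rank correlations with covariates, Benjamini–Hochberg FDR within
explicit test families, Kruskal–Wallis tests, CBCL T-score banding
(normal < 60, borderline 60–63, clinical > 63), and radiological
brain-injury grading rules.

## Worked example

```python
import numpy as np
from neoconn import (SimulationConfig, simulate_cohort, DesignSpec, nbs_test,
                     age_adjust, core_periphery_partition, Connectome)

# a 40-infant cohort with a 12-edge frontal-style subnetwork in which
# lower connectivity tracks higher externalizing scores (beta = -4)
ring = [(0, 40), (1, 40), (1, 41), (2, 41), (2, 42), (3, 42),
        (3, 43), (4, 43), (4, 44), (5, 44), (5, 45), (0, 45)]
cfg = SimulationConfig(n_subjects=40, seed=7,
                       effect_edges=tuple(ring), effect_beta=-4.0)
cohort = simulate_cohort(cfg)

scores = cohort.cohort
adj = age_adjust(scores["externalizing_raw"], scores["corrected_age_followup"])
scores["externalizing_adj"] = adj["age_adjusted"]

design = DesignSpec(
    predictor="externalizing_adj",
    covariates=("ga_birth", "sex", "injury_rating",
                "cognitive_composite", "imd", "pma_scan"),
    direction="negative", t_threshold=3.1, n_permutations=1000, seed=1,
)
result = nbs_test(scores, cohort.connectomes, design)
top = result.components[0]
print(f"largest component: {top.extent} edges on {len(top.nodes)} nodes, "
      f"FWE p = {top.p_fwe:.4f}")

truth = set(cohort.truth["effect_edges"])
recovered = set(top.edges)
print(f"overlap with planted subnetwork: "
      f"{len(recovered & truth)}/{len(truth)} edges recovered")

mean_w = np.mean([c.weights for c in cohort.connectomes], axis=0)
group = Connectome("group_mean", mean_w, cohort.connectomes[0].node_ids)
part = core_periphery_partition(group, seed=2, n_restarts=50)
print(f"core-periphery partition: {part.n_core} core / {part.n_periphery} "
      f"periphery, quality = {part.quality:.3f}")
```

prints

```
largest component: 12 edges on 13 nodes, FWE p = 0.0010
overlap with planted subnetwork: 11/12 edges recovered
core-periphery partition: 25 core / 68 periphery, quality = 0.343
```

The permutation test flags a single significant component whose edges
almost exactly match the planted subnetwork (11 of its 12 edges, plus
one false edge; FWE p is at the resolution limit of 1,000 permutations).
The data-driven partition recovers a core that lies entirely inside the
34-region planted core.

The same analysis runs from the shell against a YAML config:

```bash
neoconn run-all --config analysis.yaml --seed 7 --out results/
```

with verbs `simulate`, `metrics`, `partition`, `associations`, `nbs` for
individual stages. A run writes every intermediate table (features,
partition, edge classification, association table with FDR, NBS edge
t-table / components / sweep summary) plus `report.json`, and is
byte-for-byte reproducible given the same config and seed.

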