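# gcnforge

Construction and multivariate comparison of **gene co-expression networks
(GCNs)** from expression matrices, with an emphasis on objective, assumption-light
choices at every step: a similarity measure that sees non-linear
co-expression, a topology-driven hard-threshold rule, and a compact
multivariate summary for comparing many networks at once.

The package is aimed at researchers who assemble co-expression networks from
heterogeneous transcriptome experiments (e.g. stress or immunity time
courses across several species) and want to compare the resulting networks
quantitatively rather than by eye.

## The method

Given a genes × samples matrix *E* of log2 expression (missing values
allowed), the workflow is:

1. **Similarity.** A symmetric matrix *S* with s<sub>ij</sub> ∈ [0, 1] from one
   of three measures: the absolute Pearson correlation (APCC), the
   non-linear correlation coefficient based on mutual information
   (NCMI = √(1 − e<sup>−2Î</sup>), with Î a Miller–Madow-debiased histogram
   estimate of I(X<sub>i</sub>; X<sub>j</sub>) in nats), or the normalized mean residue
   similarity (NMRS), which is invariant to shifts and positive scalings.
   NCMI is the recommended default: it detects quadratic and other
   non-monotone co-expression that Pearson correlation misses.

2. **Threshold selection.** For each τ on the grid 0.01 … 0.99 (step 0.01)
   the adjacency a<sub>ij</sub> = 1{s<sub>ij</sub> ≥ τ} is built and the observed average
   clustering coefficient

   C(τ) = (1/K) Σ<sub>k<sub>i</sub>>1</sub> 2D<sub>i</sub> / (k<sub>i</sub>(k<sub>i</sub> − 1))

   is contrasted with its expectation for a degree-matched random graph

   C<sub>r</sub>(τ) = (k̄<sub>d</sub> − k̄)² / (k̄³ N)

   (N connected nodes, k̄ mean degree, k̄<sub>d</sub> mean squared degree). The
   selected threshold τ\* is the **first local maximum of |C(τ) − C<sub>r</sub>(τ)|**;
   the absolute value extends the classical rule to heterogeneous networks
   where C < C<sub>r</sub> throughout the scan.

3. **Characterization.** Each network is summarized by eight variables:
   clustering coefficient (CC), betweenness centralization (Cen), degree
   heterogeneity (Het = CV of the degrees), density (Den), nominal
   assortativity of GO and PFAM annotation labels (AsG, AsP), tolerance to
   removal of the top 5 % hubs measured as a ratio of mean shortest-path
   lengths (Tol), and the point-biserial correlation between degree and the
   presence of immunity-associated domains (KI).

4. **Comparison.** The networks × 8 table is z-scored and decomposed by PCA
   (correlation matrix); networks are clustered on the retained component
   scores by seeded K-means with the number of clusters chosen from the BIC
   curve BIC(k) = n ln(W<sub>k</sub>/n) + k ln n by the elbow heuristic.

A synthetic-data module generates all the fixtures with known ground truth:
power-law networks with target degree heterogeneity CV(k) and clustering,
similarity matrices with a known planted threshold, expression matrices
with planted linear / inverted / quadratic / shifted modules, and
module-enriched annotations.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from gcnforge import CoexpressionNetwork, characterize, simulate_expression
from gcnforge.synthetic import (NetworkSimSpec, recovery_experiment,
                                simulate_annotations)

# 200 genes in four 50-gene co-expression modules, 200 samples
E = simulate_expression(
    200, 200,
    [(50, "linear"), (50, "inverted"), (50, "quadratic"), (50, "shifted")],
    noise_sd=0.3, seed=42)

est = CoexpressionNetwork(measure="ncmi").fit(E)
net = est.network_
print(f"tau* = {est.tau_star_:.2f}; network: {net.n_nodes} genes, {net.n_edges} edges")

modules = {g: i // 50 for i, g in enumerate(E.index)}
degrees = dict(zip(net.gene_ids, net.degrees()))
ann = simulate_annotations(net.gene_ids, module_assignments=modules,
                           enrichment=0.8, immunity_fraction=0.15, seed=7,
                           degrees=degrees, degree_bias=1.5)
row = characterize(net, ann, metadata={"network_id": "demo"})
print(row[["CC", "Cen", "Het", "Den", "AsG", "AsP", "Tol", "KI"]]
      .astype(float).round(3).to_string())

res = recovery_experiment(NetworkSimSpec(500, 2.0, 2.86, 0.02),
                          tau_true=0.7, n_reps=10, seed=1)
print(f"recovery: eta = {res.eta:.3f} over {len(res.replicates)} replicates")
```

prints

```
tau* = 0.54; network: 200 genes, 4900 edges
CC     1.000
Cen    0.000
Het    0.000
Den    0.246
AsG    0.570
AsP    0.569
Tol    1.000
KI     0.000
recovery: eta = 0.000 over 10 replicates
```

The scan lands on τ\* = 0.54 and the resulting network contains **exactly**
the 4 × C(50, 2) = 4,900 within-module gene pairs — the four planted
modules, including the quadratic one that Pearson correlation cannot see,
and nothing else. The four 50-cliques explain the characterization row:
CC = 1 and Het = 0 (every node closes all triangles and has degree 49),
Den = 4900/19900 ≈ 0.246, moderate annotation assortativity (AsG ≈ 0.57
at 80 % term enrichment), Tol = 1 (removing hubs from a clique does not
stretch paths) and KI = 0 (degrees are constant, so no degree–immunity
correlation exists). The last line is a threshold-recovery experiment on
simulated scale-free networks (CV(k) = 2.86, C = 0.02): the selection rule
recovers a planted τ = 0.70 exactly in all 10 replicates.

The same workflow is scriptable from the shell:

```sh
gcnforge simulate expression e.tsv --genes 200 --samples 200 \
    --module 50:linear --module 50:quadratic --seed 42
gcnforge similarity e.tsv s.tsv --measure ncmi
gcnforge network s.tsv mynet          # writes mynet.sif/.edges.tsv/.graphml
gcnforge characterize mynet.edges.tsv row.csv
```

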