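# graphmm

Local false-discovery rates for two-group comparisons of graph-associated
data — voxel-wise brain imaging being the motivating case.  When the
signal distinguishing two groups (say, cognitively normal vs mild
cognitive impairment) lives on spatially coherent clusters of voxels,
testing each voxel in isolation wastes that structure.  `graphmm` scores
each vertex of a known graph with the posterior probability that its group
means agree, under an empirical-Bayes mixture that lets neighboring
vertices share parameters.

## The model in brief

For a graph `G = (V, E)` with two-group data `X` (N × M_X) and `Y`
(N × M_Y), the test at vertex `v` is `H_0v: mu_Xv = mu_Yv`.  The mixture
runs over **graph-respecting partitions** `Psi = {b_1..b_K}` of a small
subgraph around `v` (every block induces a connected subgraph) paired with
block shift indicators `Delta`.  Within block `b_k`, group means are
`phi_k` and `phi_k + delta_k Delta_k`.  Covariances are integrated out
analytically against inverse-Wishart priors (a matrix-T likelihood);
free block means are marginalized by Laplace approximation; and

    l_v = P(H_0v | X, Y)
        = sum over (Psi, Delta) of P(Psi, Delta | X, Y) 1[v's block unshifted]

is the local FDR.  Reporting `L(c) = {v : l_v <= c}` bounds the expected
false-discovery proportion of the list by the mean of its `l_v` values.
Graph restriction keeps the mixture exact and small: a 3×3 lattice has
1434 graph-respecting partitions versus B(9) = 21 147 set partitions.

Hyperparameters (`mu0, tau2, delta0, sigma2, df, A, B, p0`) are estimated
once from the whole graph by moment-based empirical Bayes; see
`docs/methods.md` for the estimators, the numerical details, and the
limitations of the synthetic test harness.

## Worked example

Simulate a 20×25 lattice slice with contiguous latent blocks of 12–14
vertices, 20% of blocks shifted by 0.6 noise-SD, 30 samples per group;
then score every vertex with its local star-neighborhood mixture:

```python
import graphmm as gm

spec = gm.scenario_preset(1, dims=(20, 25), M_X=30, M_Y=30, seed=7)
data, truth = gm.simulate_scenario(spec)
result = gm.run_graphmm(data, spec.dims, neighborhood="star2d")

hits = gm.discovery_list(result, c=0.05)
ev = gm.empirical_fdr_tpr(hits, truth.is_null)
print(f"discoveries at l_v <= 0.05 : {hits.size}")
print(f"controlled FDR             : {gm.controlled_fdr(result, hits):.4f}")
print(f"empirical FDR (truth known): {ev.empirical_fdr:.4f}")
print(f"true positive rate         : {ev.tpr:.3f}")
```

prints

```
discoveries at l_v <= 0.05 : 40
controlled FDR             : 0.0118
empirical FDR (truth known): 0.0250
true positive rate         : 0.500
```

Forty vertices are reported at the 5% threshold; the controlled FDR
(mean `l_v` on the list, computable from data alone) bounds the realized
error rate, and the empirical FDR — scored against the simulation's
ground truth — stays below the nominal 5%.  The per-voxel Welch-t
baseline with Benjamini–Hochberg correction on the same data rejects 26
vertices (TPR 0.308 vs 0.500): the blocking structure is worth real power.

The same pipeline is available from the shell:

```sh
graphmm simulate --scenario 1 --dims 20x25 --seed 7 --outdir sim/
graphmm run --x sim/X.tsv --y sim/Y.tsv --dims 20x25 --nbhd star2d --outdir out/
graphmm partitions --lattice 3x3        # 1434, median 4 blocks, size PMF
graphmm toy --p0 0.8 --pblock 0.8       # FDR-vs-list-size curve tables
```

`run` writes a TSV of `vertex_id, x, y, z, lfdr, discovered_at_0.05`
(optionally a NIfTI volume of `l_v`); real data enter as delimited
matrices or per-sample NIfTI volumes.

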