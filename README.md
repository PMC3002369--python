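# conclust — merged consensus clustering for expression data

When expression profiles (genes × conditions, or patients × genes) are
partitioned with a clustering algorithm, two questions are usually left
unanswered: *how stable are the clusters under perturbation of the data*,
and *would a different algorithm have told a different story*?  `conclust`
answers both with a resampling framework:

1. **Consensus clustering.**  Rows are repeatedly subsampled (default: 80 %
   of rows, 100 iterations) and re-clustered.  Each iteration contributes a
   binary *connectivity* matrix (1 where two sampled features share a
   cluster) and a binary *indicator* matrix (1 where two features were drawn
   together).  Their summed quotient is the consensus matrix ℳ, whose
   (i, j) entry is the empirical frequency with which features i and j
   co-cluster, given the opportunity.

2. **Robustness.**  Against a reference partition (the same algorithm run on
   the full data), each cluster k with member set *I_k* (size *N_k*) gets a
   cluster robustness and each member a membership robustness:

       m(k)   = Σ_{i<j ∈ I_k} ℳ(i,j) / ( N_k (N_k − 1) / 2 )
       m_i(k) = Σ_{j ∈ I_k, j≠i} ℳ(i,j) / ( N_k − 1 )

   Low m_i(k) flags unreliable members (outliers); m(k) is exactly the mean
   of its members' m_i(k).

3. **Merging.**  Consensus matrices from *different algorithms* at the same
   k are combined by weighted elementwise averaging.  Because algorithm
   families fail differently — agglomerative hierarchical clustering is
   outlier-sensitive, k-medoids is outlier-tolerant — the merge penalises
   structure that only one algorithm believes in, and the merged matrix can
   be cast onto any reference structure for directly comparable robustness.

4. **Cluster number.**  For each candidate k, the empirical CDF of the
   off-diagonal consensus values,
   `CDF(c) = Σ_{i<j} 1{ℳ(i,j) ≤ c} / (N(N−1)/2)`, is integrated stepwise
   over its distinct sorted values x₁ < … < x_m,
   `AUC = Σ_{i=2..m} (x_i − x_{i−1}) · CDF(x_i)`; a perfectly consistent
   clustering gives AUC = 1.  The change in AUC as k varies (ΔK) peaks at
   the best-supported cluster number.

Built-in backends: agglomerative hierarchical (average/complete/single/ward
linkage), k-means (Lloyd, plus the MacQueen online variant), and a
classical PAM k-medoids.  Any other algorithm can be registered through the
runner contract in `conclust.algorithms`.  Consensus matrices can also be
re-used as distance matrices (`D = 1 − ℳ`) for a second round of
clustering.

## Worked example

Simulate a noisy four-profile expression matrix (120 genes × 4 conditions:
25 genes around each of four base profiles, plus 20 "spike" genes around
four deviant profiles, Gaussian noise σ = 0.1), then run the full analysis
with all three algorithms over k = 2..7:

```sh
conclust simulate --n-per-profile 25 --sigma 0.1 --seed 0 --out demo.tsv
conclust run --input demo.tsv --kmin 2 --kmax 7 --iterations 100 \
             --seed 0 --outdir demo_run
```

which prints:

```
estimated k (hierarchical): 6
estimated k (kmeans): 7
estimated k (kmedoids): 4
estimated k (merge): 4
outputs written to demo_run
```

The merged consensus matrix recovers the true cluster number (4), as does
k-medoids; the single-algorithm hierarchical and k-means sweeps are misled
by the spiked outliers.  The ΔK table for the merge
(`demo_run/deltak.tsv`) shows the peak at k = 4:

```
 k   auc  delta_k
 2 1.000    1.000     (seed entry, excluded from the peak search)
 3 0.652   -0.348
 4 0.722    0.107  <- peak
 5 0.758    0.050
 6 0.795    0.048
 7 0.810    0.019
```

Casting the merge onto each algorithm's k = 4 reference structure exposes
the hierarchical failure mode: under the hierarchical reference the cluster
that fuses base profiles 3 and 4 collapses to cluster robustness 0.62 while
the three clean clusters stay at 0.97–1.00
(`demo_run/robustness_merge~hierarchical_k4.tsv`); under the k-medoids
reference all four clusters stay robust (0.92–1.00) and the spiked genes
surface as low-membership-robustness outliers in the boxplots
(`demo_run/plots/`).

The same `run` command drives real data: e.g. for a patient-stratification
matrix, `--transpose --top-variance 200` clusters patients on the 200
most variable genes, and `--unitise l2` makes profile-shape (rather than
magnitude) the basis of time-course clustering.

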