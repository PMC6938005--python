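# tnwclust

Stratify subjects by the *shape and timing* of their event histories.

`tnwclust` is for longitudinal data in which each subject experiences a
sequence of discrete events — the motivating case is patients switching
between biologic therapies, where each switch has a drug symbol and a
time since the previous switch. The package aligns every pair of
subjects with the **temporal Needleman–Wunsch** (TNW) algorithm, turns
the alignment scores into a distance matrix, clusters it
hierarchically, and uses **bootstrap resampling** both to choose how
many clusters the data support and to measure how stable each cluster
is. Final clusters are summarized as transition graphs with median
switch times.

## The method

A subject's history is a *prefix-encoded* (PE) sequence
`0.A,t₁.B,t₂.C,…` — alternating inter-event durations and state
symbols, starting at time 0, optionally ending in the censoring symbol
`Z` (outcome of the last state unobserved). Two PE sequences x, y are
aligned globally by dynamic programming:

```
H(i,j) = max ⎧ H(i−1,j−1) + s(xᵢ,yⱼ) − Tₚ·|tₓ,ᵢ − t_y,ⱼ|
             ⎨ H(i−1,j) − g
             ⎩ H(i,j−1) − g
```

with match/mismatch score s (defaults 1 / −1.1), gap penalty g, and
temporal penalty Tₚ (default 0.25) applied to the absolute difference
of the aligned events' preceding durations. With Tₚ = 0 this is the
classic Needleman–Wunsch. Pairwise scores fill a similarity matrix S;
distances are D = −S + a·**11**ᵀ with a = maxᵢ<ⱼ Sᵢⱼ, so the most
similar pair sits at distance 0.

D is clustered agglomeratively (single, complete, average, centroid or
Ward linkage). The number of clusters k is selected by bootstrapping:
resample subjects with replacement M times, re-cluster each resample,
and compare the resampled partition with the original at every
candidate cut q using five indices — Rand, adjusted Rand (AR),
Fowlkes–Mallows, Jaccard, adjusted Wallace. The q with the most
frequent highest mean index wins (ties: smallest AR standard
deviation). Each final cluster then gets stability measures τ\*
(Jaccard), γ\* (recovery rate) and η\* (Dice) against its best-matching
cluster in every bootstrap replicate.

A continuous-time Markov chain generator (`tnwclust.synthetic`)
produces labelled datasets — exponential sojourns plus an embedded jump
chain per cluster — for validating the whole pipeline against known
ground truth.

## Worked example

```python
import tnwclust as t

spec1, spec2 = t.well_separated_pair()     # two CTMCs: A↔B fast vs C↔D slow
ds = t.make_two_cluster_dataset(spec1, spec2, n_per_cluster=20, seed=3)
print(t.format_pe(ds.sequences[0]))        # e.g. "0.B,0.256….A,4.254….B,…"

config = t.SweepConfig(g_min=0.7, g_max=0.7, g_step=1.0, M=100,
                       k_min=2, k_max=6, seed=3)
result = t.run_sweep(ds.sequences, config)
print(result.selected_k)                                   # 2
print(t.compare_partitions(result.partition, ds.labels))   # AR = 1.0
print(result.gap_results[0].index_stats.mean_table().round(3))
```

```
    Rand     AR     FM  Jaccard     AW
q
2  0.995  0.989  0.995    0.990  0.990
3  0.922  0.835  0.899    0.827  0.838
4  0.842  0.603  0.714    0.559  0.669
5  0.856  0.586  0.680    0.521  0.610
6  0.869  0.589  0.673    0.513  0.570
```

Every index peaks at q = 2, so the pipeline selects two clusters, and
the selected partition matches the generating labels exactly (adjusted
Rand 1.0). The stability report for the two clusters shows median
τ\* = γ\* = 1.0 with standard deviations ≈ 0.02 — both clusters are
found again in essentially every resample. A transition-graph summary
of cluster 0 puts almost all probability on the A↔B edges
(`B->A p=0.41 median=1.21`, `A->B p=0.34 median=1.18`), the generating
regime of chain 1.

The same pipeline is available from the shell:

```
tnwclust preprocess visits.csv -o seqs.tsv --time-mode dates
tnwclust run seqs.tsv --gap-min 0 --gap-max 1 --gap-step 0.1 -M 1000 -o out/
tnwclust visualize seqs.tsv out/partition.csv -o out/graphs --format DOT
```

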