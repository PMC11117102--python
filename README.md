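# frustnet

Triadic frustration analysis of signed functional brain networks.

Resting-state functional connectivity, taken with its signs, defines a
complete *signed* graph over brain regions: a positive link where two
regions coactivate synchronously, a negative link where they are
antisynchronous. Under structural balance theory (Heider;
Cartwright–Harary) a triangle with an **odd number of negative links** is
*frustrated* — an unstable, conflictual arrangement that keeps the network
from settling into a low-energy configuration. `frustnet` measures which
elements of the brain network carry these frustrations: it enumerates all
frustrated triads of each subject's network and compares, across subjects,
each element's observed participation with its expectation under uniform
placement of frustrations.

It is written for network-neuroscience researchers who want a tested,
reusable implementation of this analysis — from (synthetic or ingested)
regional time series all the way to group-level significance maps —
without any neuroimaging downloads.

## The model

For a subject with `N` regions, time series are truncated to a common
length (default 147 points), correlated pairwise (Pearson), and reduced to
signs — a complete signed graph with no thresholding. With `N_frust` the
number of frustrated triads found among the `C(N,3)` triangles, the
uniform-placement nulls are pure counting:

| element | observed | analytic null |
|---|---|---|
| region | # frustrated triads containing it | `3 N_frust / N` |
| connection | # frustrated triads containing it | `3 N_frust / C(N,2)` |
| network `T` (within) | triads with 3 nodes in `T` | `C(N_T,3)/C(N,3) · N_frust` |
| network `T` (between-I) | 2 nodes in `T` | `C(N_T,2)(N−N_T)/C(N,3) · N_frust` |
| network `T` (between-II) | 1 in `T`, 2 in one other net | `Σ_{i≠T} N_T C(N_i,2)/C(N,3) · N_frust` |
| network `T` (between-III) | 1 in `T`, 2 in two distinct nets | `Σ_{i<j≠T} N_T N_i N_j/C(N,3) · N_frust` |
| hemisphere (all-H) | triads entirely in hemisphere H | `C(N_H,3)/C(N,3) · N_frust` |
| hemisphere (two-H) | exactly 2 nodes in H | `C(N_H,2)(N−N_H)/C(N,3) · N_frust` |

Group inference is non-parametric: Wilcoxon matched-pairs signed-rank
tests of actual vs null per element (effect size `r = Z/√n`),
Kruskal–Wallis across life-span stages (`η² = (H−k+1)/(n−k)`),
Benjamini–Hochberg FDR per analysis level, and effect bands (paired `r`:
0.1/0.4/0.6; `η²`: 0.01/0.06/0.14). The `WBR` statistic
`(WC/BC)/(WC0/BC0)` summarizes whether a flagged edge set is predominantly
within-network (WBR > 1) or between-network (WBR < 1), and a
bin-normalized Shannon entropy with a 1,000-shuffle null tests whether a
significance pattern clusters in specific canonical networks.

## Worked example

```python
import frustnet as fn

part = fn.generate_partition(60, [6] * 10, (30, 30), seed=1)
spec = fn.CohortSpec({s: 6 for s in fn.LIFESPAN_STAGES}, seed=42)
cohort = fn.generate_cohort(spec, part)

net, fs, rows = fn.run_subject(cohort[0])
print(net.negative_fraction, fs.n_frust, fs.n_triads_total)

report = fn.run_group(cohort, fn.PipelineConfig(seed=42))
print(report.wbr_results[report.wbr_results.stage == "all"])
```

This prints, for the first subject, a negative-link fraction of `0.481`
and `N_frust = 12018` of the 34,220 triads (so the uniform-placement null
for any single region is `3·12018/60 ≈ 600.9` frustrations). At the group
level the pooled analysis flags 472 connections as significantly
*low*-contributed and 79 as significantly *high*-contributed, and their
within/between ratios separate cleanly:

```
WBR low_contributed:  5.031   (predominantly within-network)
WBR high_contributed: 0.000   (exclusively between-network)
```

i.e. connections inside canonical networks stay out of frustrations while
frustrating connections run between networks. Both connection patterns are
non-random by the entropy shuffle test (`p ≈ 0.001` with 1,000 shuffles).

The same pipeline is available from the shell:

```sh
frustnet simulate --outdir cohort --n-regions 60 --subjects-per-stage 6
frustnet run-all --manifest cohort/manifest.csv --outdir report
```

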