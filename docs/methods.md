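# Methods

## Signed network construction

Each subject's regional time series (regions × time points) are truncated
to the first `n_timepoints` columns (default 147, the common-length
convention for pooled multi-site resting-state data with a 2 s repetition
time), pairwise Pearson-correlated, and reduced to link signs. The
resulting graph is complete: no threshold is applied anywhere, because a
threshold appropriate for positive correlations is not appropriate for the
(much smaller) negative ones, and the sign itself is the object of study.
Correlation matrices are computed in double precision and symmetrized by
averaging the two triangles before sign-taking.

Exactly-zero correlations are almost surely absent from empirical data but
possible in constructed inputs; the `zero_policy` decides them. The
default maps 0 → +1, which is conservative: a positive link alone can
never create a frustration. Alternatives map 0 → −1 or drop every triad
containing a zero link (`"drop"` stores the sign as 0 and the enumerator
skips those triads). The affected link count is logged.

Global-signal regression (OLS residual of each region against the
across-region mean plus intercept) is available but **off by default**:
it manufactures negative correlations by construction and therefore
changes the frustration structure being measured. A constant global
signal degenerates to demeaning, with a warning.

## Frustration enumeration

A triad is frustrated iff the product of its three link signs is −1,
equivalently iff it has an odd number of negative links. Enumeration
sweeps the smallest node index and evaluates all `C(N−i−1, 2)` sign
products per sweep with vectorized index arithmetic, in lexicographic
order. At N = 268 this is ~3.17 M products and runs in about a second;
the test suite pins the enumerator to an independent brute-force triple
loop on hundreds of random graphs.

Element contributions are counted directly from the enumerated triads.
Conservation identities (node sums and edge sums both equal `3 N_frust`;
the four hemisphere states tile `N_frust`; the four formation types of a
network tile the frustrations touching it) are asserted in tests.

## Analytic nulls

All nulls are expectations under uniform random placement of the observed
`N_frust` frustrations over the `C(N,3)` triads, i.e. pure hypergeometric
counting over partition sizes (formulas in the README table). Numerators
are computed with exact integer binomials; the single floating division
happens last. The four hemisphere nulls sum to `N_frust` for any split by
the identity `C(a,3)+C(b,3)+C(a,2)b+C(b,2)a = C(a+b,3)`.

Hemisphere nulls are keyed by hemisphere label (the all-right null uses
the right-hemisphere count), the only self-consistent convention when a
description and a formula could be read to disagree about state numbering.

## Group statistics

* **Paired tests** — Wilcoxon matched-pairs signed-rank, two-sided, zero
  differences dropped. p is exact for ≤ 25 informative pairs without tied
  magnitudes, otherwise a tie-corrected normal approximation with
  continuity correction. The effect size is `r = Z/√n` over informative
  pairs, signed positive when actual exceeds null; Z always comes from the
  (tie-corrected, continuity-corrected) normal approximation, the standard
  paired-r convention. Elements with fewer than 5 informative pairs are
  reported degenerate (p = 1, r = 0) rather than tested.
* **Stage comparisons** — tie-corrected Kruskal–Wallis with rank
  `η² = (H − k + 1)/(n − k)`; negative values (possible at small H) are
  reported as-is and band as negligible.
* **FDR** — Benjamini–Hochberg step-up, one family per analysis level ×
  stage (the per-figure convention); configurable by calling the stats
  layer directly. Note that BH adjustment is monotone and capped but *not*
  idempotent; tests assert the true step-up properties.
* **Bands** — paired |r|: small 0.1, medium 0.4, large 0.6; η²: 0.01 /
  0.06 / 0.14. Values below the small threshold report "negligible" (an
  explicit extension of the three-band scheme). An element is *flagged*
  only when FDR-adjusted p < α (default 0.05) **and** its band reaches the
  required band (default large); direction follows the sign of r.
* **WBR** — `(WC/BC)/(WC0/BC0)` of any edge set against the partition's
  maximum possible within/between counts. BC = 0 yields `inf` and an
  empty set `nan`, both flagged via `WBRResult.defined`, with raw counts
  always reported.

## Pattern entropy

States are canonical networks (regional patterns) or unordered network
pairs (connection patterns). Flag counts per state are normalized by the
state's bin size (regions in the network; possible edges of the pair) and
then renormalized to probabilities — the renormalization guarantees a
proper distribution, which a bin-size division alone does not. Entropy is
Shannon's, in nats, with `0·ln 0 := 0`. The shuffle null permutes the flag
vector uniformly over elements (flag count preserved, default 1,000
shuffles); the one-sided lower-tail p uses the `(1 + #{H_null ≤ H})/(1 + n)`
permutation correction, so clustering — abnormally low entropy — gives
small p and p is never exactly 0. A pattern covering every element is
degenerate (p = 1).

## Synthetic cohorts

The generator emulates what the analysis assumes about preprocessed,
parcellated resting-state data, not the data themselves: zero-mean
multivariate normal time series with a **block-constant** correlation
matrix. Within-network coupling is `rho_within` (default 0.4); coupling
between networks is block-constant per network pair, generated by grouping
the canonical networks into `n_systems = 3` super-systems — same-system
pairs couple at `rho_between_pos = +0.15`, cross-system pairs at
`rho_between = −0.05`. This mirrors the empirical geography in which
sensory/attention networks correlate positively with each other while
task-positive and default-mode systems anticorrelate, and it keeps the
matrix positive definite with margin `1 − rho_within` for every partition
used here. A scalar `rho_between` (set `n_systems = 1`) or a fully
user-supplied coupling matrix are one-argument switches. Infeasible
combinations are repaired by convex shrinkage toward the identity with the
weight logged, or rejected when shrinkage is disallowed. Optional
`noise_sd` adds white noise, attenuating all correlations by
`1/(1 + noise_sd²)`.

With T = 147 samples the sampling noise of a correlation is ≈ 0.08, so
cross-system links (true coupling −0.05) come out negative in roughly
three quarters of draws and same-system links essentially never do:
negative links are almost exclusively between-network, within-network
links essentially all positive — the sign geography the analysis rests
on. The *overall* negative-link rate (≈ 0.5 at these defaults) is not
calibrated to any empirical value; consequently passing tests demonstrate
correctness of the machinery and directional reproduction of the
qualitative pattern, not quantitative agreement with real cohorts. The
generator also omits everything a scanner adds: no hemodynamics, no
motion, no physiological noise, no site effects.

Default dimensions are small for fast tests (N = 60, 10 networks,
T = 147); a 268-region preset (`shen268_partition`, 10 networks, 135
left / 133 right regions) exercises full scale. Per-subject seeds derive
deterministically from the cohort master seed (`SeedSequence` spawn
keys), so cohorts are reproducible and extendable; ages are drawn
uniformly within each life-span stage band (childhood 6–12, adolescence
12–18, early adulthood 18–40, middle adulthood 40–65, late adulthood
65–80).

Label-volume fixtures for the atlas projection slice a 3-D grid into one
slab per network and one sub-slab per fine parcel; a jitter fraction swaps
voxels between parcels of different networks to degrade the overlap while
keeping ground truth defined.

## Atlas projection

Dice `C_ij = 2 h_ij/(a_i + b_j)` from exact voxel counts; label 0 is
background and never participates; volumes must share a grid (resampling
belongs to neuroimaging tooling upstream). Assignment is the argmax per
parcel; explicit overrides (e.g. subcortical structures, brain stem,
cerebellum when the canonical atlas is cortical-only) take precedence;
exact ties resolve to the lowest column index and are logged, and
zero-overlap parcels without an override are flagged unassigned.

## Pipeline defaults and determinism

`PipelineConfig()` reproduces the main-analysis conventions: 147 time
points, GSR off, zero → +1, α = 0.05, large band required, 1,000 entropy
shuffles, paired-stats families per level × stage. Stages below 5 subjects
are skipped with a warning (the signed-rank minimum); the pooled "all"
group pools subjects across stages (pooling, rather than aggregating
stage-level results, is the package's choice and is configurable via
`pool_all`). Everything downstream of a fixed config and seed is
deterministic; `GroupReport.digest()` hashes all result tables for
verification, and runs write a manifest with the config and its hash.

## Problem sizes used in verification

The packaged checks run at desk scale, chosen to finish in minutes while
leaving no asymptotic assumption untested: 200 random graphs at N ≤ 25
against brute force; 2,000 node relabelings at N = 60 (4 networks) for the
null formulas (agreement within 3 Monte-Carlo standard errors); 100 random
partitions for the exact combinatorial identity; 200 simulated null-true
cohorts of 40 subjects for type-I calibration; a 30-subject modular cohort
for the WBR directions; 200 replicates for entropy-p calibration; and one
full 268-region subject for the scale check.

## Known limitations

* The synthetic generator reproduces sign geography, not empirical
  negative-link rates, regional heterogeneity, or stage effects; stagewise
  Kruskal–Wallis results on synthetic cohorts are null by construction.
* Only triads are analyzed; longer frustrated cycles, balance-energy
  measures and frustration-index optimization are out of scope.
* Atlas projection assumes same-grid volumes.
* The WBR of a flagged edge set depends on the flagging thresholds
  upstream; it is reported with its raw counts so other thresholds can be
  recomputed.
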