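# Methods

This document describes the statistical model behind `tknet`, the meaning
and defaults of every parameter, the synthetic data generator, and the
numerical choices made in the implementation.

## 1. Data model

Inputs are three tables keyed by sample id:

- **Counts** — integer ASV counts, samples × ASVs (files may be stored
  transposed; orientation is auto-detected against the metadata).
- **Host** — continuous host parameters, samples × parameters.  Missing
  values are allowed; a parameter measured in only one experiment is
  flagged and excluded from cross-experiment standardization.
- **Metadata** — per sample: `experiment`, `group`
  (Control / Treatment), and `cohort` (birth cohort / litter).

The design is two independent experiments, each with a control and a
treatment arm, giving four analysis groups.  Each group needs at least 4
samples (Spearman p-values are meaningless below that).

## 2. Preprocessing

Microbes, in order:

1. **Singleton removal** — ASVs whose total count across all samples is
   exactly 1 are noise and dropped.
2. **Cumulative-abundance filter** — ASVs are ranked by total abundance
   and the smallest prefix covering ≥ 99.5% of all reads is kept.  This
   removes the long tail of rare ASVs that cannot support correlation
   estimates.
3. **Relative abundance** — counts per million within each sample,
   removing sequencing-depth differences.
4. **Quantile normalization, per experiment** — each sample's k-th order
   statistic is replaced by the within-experiment mean of k-th order
   statistics; ties receive the average of their reference values.  After
   this step all samples of an experiment share one value distribution
   (sorted vectors identical to numerical precision), which makes rank
   correlations comparable across samples.
5. **log2(x + 1)** — variance stabilization; the pseudocount (default 1)
   keeps zeros at zero.

Hosts, in order:

1. **Cohort normalization** — each value is divided by its birth-cohort
   mean (or median, configurable), removing litter effects.  A cohort mean
   of exactly zero is a hard error (the ratio would be undefined).
2. **Per-experiment z-score** — parameters measured in both experiments
   are standardized within each experiment so that values are comparable
   across studies with different instruments or units.

Phylum-level summaries (`aggregate_phylum`, Bacteroidetes/Firmicutes
ratio) are provided for descriptive output only; they play no role in edge
inference.  The common misspelling "Bacteriodetes" and the newer name
"Bacteroidota" are accepted.

## 3. Edge inference

For every feature pair, Spearman's ρ and a two-sided p-value (t
approximation on n−2 df, average ranks for ties) are computed **within
each of the four groups**.  A pair becomes a kept edge only if it passes,
in order:

1. **Defined** — no group has a constant feature (NaN correlation).
2. **Sign consistency** — ρ strictly positive in all groups or strictly
   negative in all groups.  A correlation that flips sign between groups
   is treated as noise.
3. **Coherence ("causality") filter** — sign(ρ) must equal
   sign(ΔA)·sign(ΔB), where Δ is the feature's treatment-response
   direction (below).  A positive correlation between a microbe that goes
   up and a parameter that goes down cannot reflect a direct interaction.
   Exactly 4 of the 8 sign combinations are coherent.
4. **Fold-change consistency** — both endpoints changed in the same
   direction in every experiment.  Directions come from median
   treatment/control fold changes on a positive scale: back-transformed
   abundances (2^x − pseudocount) for microbes, stage-1 cohort-normalized
   values for hosts.  A fold change of exactly 1, or a zero control
   median, leaves the direction undefined and the feature inconsistent.
5. **Prefilter (microbe–host only)** — every per-group p-value must be
   below 0.6.  This deliberately weak gate removes pairs with essentially
   no evidence in some group before FDR.  A configurable rescue list can
   exempt named edges.
6. **FDR** — surviving candidates are pooled across groups with a
   Fisher-Z fixed-effect meta-analysis: zᵢ = atanh(ρᵢ) with weight
   wᵢ = nᵢ − 3, pooled statistic z̄/SE with SE = 1/√Σw, two-sided normal
   p.  Benjamini–Hochberg adjustment is applied **within each edge
   class** with class-specific thresholds: microbe–microbe 0.05,
   microbe–host 0.15 (weaker cross-kingdom signals are expected),
   host–host 0.10.

Every candidate pair — kept or not — is written to `edges.tsv` with all
per-group statistics, all filter flags, and the first failing filter, so
any edge decision can be audited.

## 4. Topology and bottleneck ranking

Nodes are the endpoints of kept edges.  Two scores are computed:

- **Degree** — incident-edge count.
- **BiBC** (bipartite betweenness centrality) — for node sets A (microbes)
  and B (hosts), BiBC(v) = Σ over pairs (s∈A, t∈B), s ≠ v ≠ t, of
  σ_st(v)/σ_st, where σ_st counts shortest s–t paths and σ_st(v) those
  through v.  Edges are unweighted for path purposes.  The implementation
  is a Brandes-style dependency accumulation run from each source in A
  with targets restricted to B — exact, O(|A|(n+m)), and validated against
  brute-force shortest-path enumeration.  Normalized BiBC divides by
  |A|·|B| and lies in [0, 1].

Candidates are ranked by normalized BiBC (descending), then degree, then
node id (a deterministic tie-break); the top 3 per node type are reported.

## 5. Null calibration

The question "is this node's (degree, BiBC) remarkable?" is answered
against the Erdős–Rényi **G(n, m)** ensemble: uniform simple graphs with
exactly the observed node and edge counts.  For each of 10,000 sampled
graphs (default), nodes are split into a uniformly random partition with
the observed group sizes (the real bipartition has no meaning on an
unlabeled random graph), and every node's degree and normalized BiBC are
pooled.  The pooled sample yields:

- a 2-D probability density over (degree, BiBC) — integer degree bins,
  50 equal-width BiBC bins;
- an empirical upper-tail probability P(degree ≥ d AND BiBC ≥ b).  A query
  beyond every pooled sample is reported as 1/pool-size, to be read as an
  upper bound ("< 1/pool-size").

Because every G(n, m) graph has exactly m edges, the pooled mean degree is
exactly 2m/n.  A `top-node` mode pools only each graph's most extreme node
instead, for calibrating maxima.

## 6. Synthetic data generator

`SyntheticConfig` defaults (chosen a priori to mimic a realistic 16S
experiment, not fitted to any outcome):

| parameter | default | meaning |
| --- | --- | --- |
| `n_experiments` | 2 | independent experiments |
| `n_samples_per_group` | 8 | per (experiment, arm) |
| `n_asvs` | 100 | ASV count |
| `n_host_params` | 10 | host parameters |
| `n_shifted_asvs` | 12 | ASVs with a planted treatment response |
| `effect_log2fc` | 1.0 | planted log2 fold change |
| `n_bottlenecks` | 1 | planted bottleneck microbes |
| `hub_link_count` | 4 | host parameters coupled to each bottleneck |
| `coupling_strength` | 0.8 | microbe→host coupling on the log scale |
| `sequencing_depth` | 50000 | multinomial reads per sample |
| `batch_sd` | 0.3 | per-experiment batch effect (log scale) |
| `noise_sd` | 0.5 | host residual noise (log scale) |

Construction:

- Baseline log abundances are normal with sd 1.5 (a realistic steep rank
  curve); within-group sample variation has log-sd 0.5.
- Shifted ASVs are drawn from the abundant half, and their shift signs
  **alternate down the abundance ranking** (with one random global flip).
  Balancing up- and down-shifts among abundant taxa keeps the compositional
  (relative-abundance) view faithful to the planted signs; an unbalanced
  draw can make an unshifted or up-shifted taxon appear depleted purely
  through closure.
- The bottleneck is the shifted ASV closest to the median abundance of
  the shifted set: abundant enough to be measured well, not so dominant
  that quantile normalization freezes its rank.
- Counts are multinomial draws at fixed depth from the per-sample
  composition.
- Each linked host parameter is `base · exp(coupling · z + noise + cohort
  + batch)`, where z is the per-experiment standardized log1p **observed
  count** of the bottleneck.  Tying hosts to the observed (not latent)
  microbe makes the planted association exact at `coupling_strength = 1,
  noise_sd = 0, batch_sd = 0`: within-group Spearman |ρ| = 1.  The planted
  edge sign is `link_sign · shift_sign`, so planted edges always satisfy
  the coherence filter.
- Cohorts (3 or 4 per experiment, round-robin) receive offsets with sd
  `batch_sd / 2`; hosts are strictly positive by construction
  (exponential form), matching the divide-by-cohort-mean normalizer.

`truth.json` records the shifted ASVs with signs, the bottleneck ids, and
the planted (microbe, host, sign) edges.

## 7. Numerical choices

- Spearman correlation is computed as Pearson on average ranks via a
  single correlation-matrix call, not per pair; p-values use the t
  approximation with p = 0 pinned at |ρ| = 1.  A constant feature yields
  NaN for its pairs only (a whole-matrix NaN, as some library routines
  produce, would silently kill every edge).
- Fisher-Z pooling clamps |ρ| = 1 to 1 − 1e−7 with a warning; groups with
  n ≤ 3 are rejected (zero or negative weight).
- The BH adjustment comes from `statsmodels.multipletests` and is verified
  against a brute-force step-up oracle.
- All randomness flows from one top-level seed through
  `numpy.random.SeedSequence.spawn`; per-stage seeds are recorded in the
  run manifest, and repeated runs are bit-identical.
- Config objects hash (SHA-256, 16 hex chars) into every output file
  header so that outputs of different configurations cannot be mixed
  silently.

## 8. Limitations

- Correlation networks are not causal graphs; the "causality" filter only
  removes sign-incoherent edges, it cannot establish direction.
- Quantile normalization attenuates rank signal when group sizes are
  small; with 8 samples per group the planted bottleneck is recovered in
  roughly 9 of 10 synthetic datasets, not all of them.  Misses come from
  per-group sign flips and ties among low-degree nodes, not from any
  single failure mode.
- The fixed-effect meta-analysis assumes one common underlying correlation
  across groups; heterogeneity is partially absorbed by the sign and
  coherence filters but not modeled.
- The G(n, m) null preserves only node and edge counts, not the degree
  sequence or bipartite structure of the observed network; tail
  probabilities are calibration aids, not p-values.
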