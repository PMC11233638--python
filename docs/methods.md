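# Methods

This note documents the models, conventions and numerical choices behind
`cerebmotif`, and what the synthetic-data generators do and do not emulate.

## Zone mapping and marginals

The seven stimulation sites (lobules II, III, IV/V, VI/VII, VIII, IX, X) map
to the four transverse zones by a fixed rule: any of II/III/IV-V → anterior;
VI/VII → central; VIII, or IX without X → posterior; X (alone or with IX) →
nodular. Two readings of the IX clause are possible when VIII, IX and X are
all connected; we take the literal one — IX's contribution moves entirely to
the nodular zone whenever X is present, while VIII keeps the posterior zone
regardless. Zone marginal probabilities divide by **all tested cells**,
including cells with no connected lobule (they respond only to
axonal-terminal stimulation); this is forced by the 26/75-style arithmetic
the marginals must reproduce.

Lobule II is excluded from connectivity tables and clustering (lateral
slices often lack it) but remains a legal label for zone mapping.

## The canonical dataset

`build_fixture()` loads a frozen 75-cell table committed to the repository
(`src/cerebmotif/data/fixture_connectivity.csv`). Its constrained properties:
75 cells, exactly 34 without any connected lobule; zone marginal counts
anterior 13, central 26, posterior 16, nodular 13; exactly three cells with
four-zone input; and every within-zone lobule pair (III·IV/V, VIII·IX)
co-occurring in more cells (11 and 14) than any cross-zone pair (max 10), so
UPGMA merges within-zone lobules first. Within those constraints the exact
composition of 1-, 2- and 3-zone cells (24/10/4, with combinations chosen to
spread across zone pairs) is a free design choice made once and frozen; the
motif statistics depend only on the zone-set counts. Per-connection
amplitudes follow the deterministic scheme 40 + 20·(anatomical index) pA
(III → 60 … X → 160) and a constant 340.8 pA terminal response; only summary
statistics depend on these.

With this dataset the four-zone pattern has expectation
75·(13·26·16·13)/75⁴ ≈ 0.1666, observed 3, fold ≈ 18.0, exact tail
P(X ≥ 3) ≈ 6.6×10⁻⁴ and BH-adjusted p ≈ 0.0099 over the 15-pattern family.

## Motif testing

* **Family**: the 15 nonempty zone combinations by default (the empty set is
  not a "zone combination"); `all` (16) and `observed` are available. The
  family size affects only the BH correction.
* **Direction**: chosen per pattern by the sign of observed − expected; ties
  (observed exactly equal to expected) report `equal` with p = 1.
* **Tails are exact** binomial sums (scipy's regularized incomplete beta),
  no normal approximation; marginals are plug-in estimates from the same
  dataset (the worked-example convention). Because the test statistic is
  discrete, the BH procedure is conservative: under the independence null
  the any-discovery rate measured over 2,000 simulated datasets is ≈0.2%,
  well below the nominal 5%.
* **Fold** is reported as missing (not infinite) when the expected count
  is 0.

## Clustering

Normalized Hamming distance (mismatch fraction over the ≥1-lobule cells,
n = 41 in the canonical dataset; a count mode exists). UPGMA recomputes
cluster distances as size-weighted means, which equals the plain average
over member pairs; ties break lexicographically on each cluster's smallest
leaf label, so dendrograms are byte-reproducible. Row (cell) clustering uses
the same operations with `axis="cells"`. Newick export uses the half-height
convention (leaf at height/2 below a merge), 12 significant digits. The
zone-concordance check assigns each clustered lobule one zone (IX →
posterior, X → nodular, i.e. each lobule's dominant contribution) and
verifies that within-zone merge heights never exceed the smallest cross-zone
merge involving either leaf.

## Topography bootstrap

OLS of y on x per zone-count group (0–4, skipping groups with <3 cells) in
two planes: rostral-caudal × ventral-dorsal and medial-lateral ×
ventral-dorsal. Conventions: R² = 1 − SS_res/SS_tot; constant y defines
R² = 0 (no explainable variance); constant x is a fit error. The bootstrap
draws same-size groups **without replacement** from all cells with
coordinates (a relabeling of real cells; with-replacement is a flag) and
reports the exceedance percentile p_boot = #{R*² ≥ R²_obs}/B with B = 50,000
by default (Monte-Carlo SE ≈ 0.001 at p = 0.05). Per-(group, plane) seeds
derive deterministically from the user seed. The ten group×plane tests are
deliberately not corrected for multiple comparisons. A ≥-comparison with
10⁻¹² slack absorbs summation-order float noise when a resample is a
permutation of the observed group.

## IPSC and spike-train features

* **Windows**: baseline = 10 ms pre-onset; response = 50 ms post-onset; the
  3 ms light pulse starts at the configured onset. All configurable.
* **Amplitude** is the maximum absolute deviation from the per-sweep
  baseline within the response window, reported as a positive magnitude
  (sign convention: magnitudes regardless of recording polarity).
* **Detection** (success/failure calls) additionally smooths the trace with
  a 0.5 ms boxcar before the peak search, so that white-noise extremes over
  the 50 ms window do not cross the θ = 3 baseline-SD threshold; measurement
  uses the raw trace. A site is responsive when ≥50% of ≥3 sweeps succeed.
  θ and the 0.5 cutoff are explicit choices (no numeric criterion exists in
  the source protocol) and remain configurable.
* **Rise time**: first crossings of 20% and 80% of the peak deviation with
  linear interpolation between samples. A one-sample step therefore
  resolves to 0.6 sampling intervals — sub-sample, not exactly zero.
* **Decay**: bounded trust-region least squares of A₁e^(−t/τ₁) + A₂e^(−t/τ₂)
  (amplitudes ≥ 0), multi-start over τ initializations {(2,20),(1,8),(5,50)} ms,
  components ordered τ₁ ≤ τ₂ to remove label switching;
  τ_w = (A₁τ₁+A₂τ₂)/(A₁+A₂) is always inside [τ₁, τ₂].
* **ISI ratio**: the interval containing the end of the light pulse divided
  by the mean of the trial's other intervals (`first_complete` mode takes
  the first interval after light offset instead). Exclusions: mean rate
  <20 Hz; ISI CV > 1 (operationalizing "bursting rather than tonic firing" —
  an explicit choice, configurable). Note the interval containing a fixed
  time point in a stationary renewal process is length-biased by 1 + CV²,
  so even unperturbed regular trains sit slightly above 1 (≈1.04 at CV 0.2).

## Puncta geometry

Per punctum, the Euclidean nearest neighbor in the union of the *other*
channels (an ordered-pair mode is not needed for the pooled curve; channel
permutation leaves the pooled distances unchanged). Cumulative fractions are
read at 17.5 µm (`soma_diameter_um`) and 100.5 µm (`dendrite_length_um`).
Aggregation reports both the mean of animal-level fractions with a t-based
95% CI and the pooled-puncta fraction, since the two answer slightly
different questions. `query_region` enables minus-sampling edge correction
(border puncta serve as neighbors only), removing the boundary bias of
finite fields. Colocalization is 100·|A∩B|/|A∪B| by default (symmetric,
conservative); per-channel denominators via flag. Analysis is 2-D.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of config + seed (numpy `default_rng`).

* **Connectivity**: independent Bernoulli per zone — exactly the null model
  of the motif test — with defaults matching the canonical marginals
  (13/26/16/13 over 75). Lobule allocation draws one lobule per zone by
  default (zone and lobule marginals coincide); `dense` mode includes each
  in-zone lobule with probability 0.7 for clustering tests. When posterior
  and nodular are both drawn, posterior is realized through VIII so the
  zone set survives the mapping rule. The `enrichment` option appends extra
  cells of a fixed pattern for power studies: +3 four-zone cells are
  detected (BH-adjusted p < 0.05) in ~64% of replicates.
* **Coordinates**: isotropic Gaussian clouds (SD 150 µm) with an optionally
  collinear group (perpendicular noise configurable to 0).
* **Sweeps**: saturating-rise × double-exponential-decay waveform with
  defaults at the measured scale (91.18 pA amplitude, rise τ 0.8 ms, decay
  3/15 ms at 0.67/0.33 weights, 2 pA noise, 0.1 ms sampling). Because the
  rise term contaminates the first ~2 ms after the peak, exact τ recovery
  fits the decay from 2 ms post-peak.
* **Spike trains**: gamma renewal (shape 1/CV²) at 50 Hz, CV 0.2 — regular
  tonic firing comfortably above the 20 Hz inclusion bound and with
  length-bias (1.04) inside the expected unperturbed band. The interval
  containing the light offset is stretched by `pause_factor`, so the
  analyzer recovers it exactly as CV → 0.
* **Puncta**: independent homogeneous Poisson processes per channel; the
  cross-channel NN distance then follows 1 − exp(−λπr²), giving an analytic
  oracle. Pooled distances come in mutually-dependent nearest-neighbor
  pairs, so goodness-of-fit is evaluated at effective sample size n/2.

Passing these recovery tests shows the estimators are correct under the
stated generative models; it does **not** validate robustness to features of
real recordings the generators omit — series-resistance drift, overlapping
spontaneous IPSCs, electrode artifacts, non-stationary firing, anisotropic
puncta clustering within longitudinal stripes, or 3-D structure collapsed
into single planes.

## Problem sizes used by the test suite

Calibration and recovery suites use 2,000 null datasets (type-I), 400
enriched datasets (power), 20 seeds × 50,000 iterations (bootstrap
recovery), 500 replicates × 1,000 iterations (percentile uniformity), 100
seeds (decay recovery), 1,000 trials (ISI calibration) and 20 Poisson
fields — sizes at which the Monte-Carlo error of each checked rate is well
below its acceptance margin.

## Known limitations

* The BH family size for the printed adjusted p of the four-zone motif is
  not uniquely recoverable from the source; with the default 15-pattern
  family the adjusted value lands at 0.0099, treated as a consistency check.
* The independence null uses plug-in marginals estimated from the tested
  dataset; no dependence-preserving permutation null is provided.
* Whether the original bootstrap sampled with or without replacement, and
  over which cell population, is not stated; both modes are provided with
  without-replacement over all coordinate-bearing cells as default.
* IPSC detection thresholds and the burst-exclusion criterion are explicit
  package choices; results depending on them should be reported with the
  settings used.
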