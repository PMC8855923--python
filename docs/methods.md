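# Methods

## Signal model and extraction

A kinome chip read is a fluorescence intensity per (sample, peptide,
exposure time). Under linear kinetics the accumulated phosphorylation grows
proportionally with exposure, so the informative quantity is the
least-squares slope of intensity on exposure time (milliseconds). The
extracted signal is

    signal = log2(1 + max(slope, 0) * slope_scale),      slope_scale = 100

The ×100 scaling places typical slopes (~0.01–1 intensity/ms) into a range
where the log2 transform is approximately linear in log kinase activity
(`log2(1+x) ≈ log2 x` for x ≫ 1) while the `1 +` stabilizes variance near
zero. Negative slopes — photobleaching, wash artifacts — are clamped to
zero because phosphorylation signal is physically non-negative; the fitted
slope and R² are retained in the diagnostics either way. A series needs at
least 3 distinct exposures to be measurable; an all-constant series has
slope 0 with R² defined as 0.

**QC ("acceptable kinetic curves and signals").** Vendor acceptance
criteria are not public, so the gate is parameterized with defaults chosen
on synthetic data: per comparison, a peptide passes iff in *every*
comparison sample the curve is measurable and either fits well
(R² ≥ `qc.min_r2`, default 0.8) or was clamped flat (slope ≤ 0, a
legitimate zero), and its maximum intensity reaches
`qc.min_max_intensity` (default 5.0 fluorescence units) in at least one
sample. The gate is monotone in both thresholds. QC is per-comparison: a
peptide may pass for one group contrast and fail for another.

## Kinase→peptide mapping

Phosphosite prediction scores (PhosphoNET/Kinexus convention, dimensionless,
roughly 0–1000) map kinases to chip peptides: per kinase, restrict to
on-chip peptides, keep scores strictly greater than
`mapping.score_threshold` (default 300), sort descending (ties broken
lexicographically by peptide id for reproducibility), keep the top
`mapping.top_k` (default 12) at ranks 1..k. In-vitro confirmed substrates
form a separate rank-0 tier: no score, never counted against the top-k
budget, and taking precedence when a peptide would appear in both tiers.
The top-k cut is applied *after* restriction to on-chip peptides, which
maximizes usable targets per kinase. Duplicate (kinase, peptide) score rows
resolve to the maximum score (conservative retention, logged).

Homology expansion transfers a site's score to chip peptides whose
±7-residue phospho-centered window matches at ungapped fractional identity
≥ 0.90 (windows compared center-aligned; length differences count as
mismatch via the longer-window denominator).

## The kinase statistic and its permutation scores

For kinase k with usable mapped set M (mapped ∩ on-chip ∩ QC-passing),
|M| = n ≥ `uka.min_peptides` (default 3; smaller sets are skipped with a
reason code):

    tau_k = (1/n) * sum_{i in M} (m_i1 - m_i2) / sqrt(v_i1 + v_i2)

with m, v the per-group sample mean and variance (ddof 1) of the log2
signal. Pooled variances below 1e-8 are replaced by 1e-8 (logged), which
caps a single peptide's standardized term at 1e4·|Δmean|. tau is invariant
to global positive scaling of the signals and antisymmetric under group
swap. n is per-kinase and data-dependent, not a design constant.

**Significance** permutes sample group labels. The comparison is two-sided
on |tau|, under which a labeling and its complement are the same test
outcome; the permutation space is therefore the set of distinct group
*partitions* (for equal group sizes each unordered split counted once),
excluding the observed partition. If that space has ≤ B elements it is
enumerated exhaustively (B_eff = its size), otherwise B_eff = B uniform
draws are taken. Excluding the observed partition rather than only the
observed labeling matters: the mirror labeling reproduces −tau exactly and
would otherwise impose a floor of 2/(B_eff+1) on the attainable p-value in
exhaustive mode and inject draw-lottery noise in sampling mode.

**Specificity** draws B random peptide sets of size n from all QC-passing
peptides (without replacement within a draw) and compares |tau| of the
random set against the observed mapping. If the chip offers no alternative
set (all passing peptides are mapped) the p-value is forced to 1 with a
warning.

Both report the pseudo-counted estimator p = (1 + b)/(B_eff + 1), b the
number of draws with |tau_perm| ≥ |tau_obs| (with a 1e-12 tolerance so
exact ties count), displayed as the score −log10(p). The **final score**
is significance + specificity, exactly; kinases with final score >
`uka.report_threshold` (default 1.5) are report-flagged, and the table is
sorted by final score (ties: |tau|, then name). A final score of 1.5
corresponds, e.g., to p ≈ 0.032 on both tests simultaneously.

The vendor-style "mean" statistic (averaging tau over random 80%
sub-samplings of the mapped set) is available behind
`uka.subsample_iters` (default 0 = off); it affects only the reported tau,
never the permutation scores.

**Reproducibility.** All randomness derives from the single run seed; each
kinase gets its own substreams via a stable CRC32 hash of its name, so
adding or removing a kinase never perturbs the others' draws. Identical
config + seed reproduce byte-identical result tables.

## Peptide-level statistics

Welch's unequal-variance t with two-sided p per QC-passing peptide,
BH-adjusted across the comparison. Degenerate cases are explicit: zero
variance in both groups with equal means → t = 0, p = 1; zero variance
with unequal means → t = ±inf sentinel with p at the machine minimum
(logged). The "differentially regulated" ranking uses |t| by default
(switchable to |delta|); the top `differential.n_top` (default 75) feed
the heatmap: per-peptide z-scores across samples (zero-variance rows become
zero, logged), rows and columns ordered by average-linkage Euclidean
hierarchical clustering with inputs pre-sorted lexicographically so the
leaf order is a pure function of the data.

## The synthetic generator: what it emulates and what it does not

`simulate_experiment` states a two-group chip world: `n_kinases` = 20
kinases, `n_peptides` = 140 peptides (a typical STK chip scale),
`samples_per_group` = 6 per group. Each kinase receives
`targets_per_kinase` = 9 true substrates with prediction scores uniform on
301–600 and `decoys_per_kinase` = 6 decoys on 50–299 — so the 300 mapping
threshold is exercised from both sides — plus `invitro_per_kinase` = 2
in-vitro substrates. Affinity is score/1000 for scored targets and 0.5 for
in-vitro entries; affinity support equals the mapping support by
construction. Group activities are 1.0 baseline with planted deltas added
in group 1.

The true log2 signal of peptide i in sample j of group g is

    s_ij = basal_i + sum_k affinity[k,i] * activity[k,g] + N(0, noise_sigma²)

with `noise_sigma` = 0.25 log2 units and basal_i uniform on 2–4 log2
units. The basal term represents background phosphorylation every chip
peptide exhibits; without it, unmapped peptides would have zero intensity
and fail the QC floor, leaving most of the chip unmeasurable. It cancels in
every group contrast, so tau, calibration and recovery are unaffected by
its level. The kinetic series inverts the extraction transform exactly —
intensity(t) = (2^s − 1)/100 · t over exposures {10, 20, 50, 100, 200} ms —
plus read noise N(0, `kinetic_noise_sigma`²), default 0.25 fluorescence
units (well below typical curve amplitudes of 5–100; at the weakest basal
signals this leaves fit R² ≈ 0.99). Optional planted QC failures are flat
pure-noise series (N(1, 0.5), never mapped) that miss the intensity floor.

The generator does **not** emulate: spot-level image artifacts, washing
effects, inter-array batch effects, heavy-tailed or correlated noise, or
kinase–kinase competition for substrates. A green recovery test therefore
establishes that the statistics recover planted activity differences under
Gaussian, independent, batch-free noise with a correct mapping — not that
any real-chip vendor pipeline is reproduced. Because target sets of
different kinases overlap (20 × 9 draws from ≤140 peptides), substrate
sharing leaks planted signal into co-mapped kinases, which is realistic and
visible in ranked tables as secondary flagged kinases.

`simulate_null` derives per-replicate seeds from (seed, replicate);
`recovery_experiment` runs the full pipeline over a delta × group-size grid
and tabulates planted-kinase rank, final score and flag counts.

## Configuration and artifacts

`RunConfig` validates a nested mapping against the full default schema —
unknown keys are fatal by name — and the resolved configuration (all
defaults materialized) is written alongside the results, sufficient to
reproduce the run. Figures (heatmap; per-kinase bars with the kinase
statistic on the left axis and the specificity score on the right) are
rendered from the emitted TSVs, never from in-memory state.

## Known limitations

- QC thresholds are conventions tuned on synthetic data, not vendor values.
- The homology window rule assumes the phospho-residue is centered in each
  reported window.
- Permutation resolution is bounded by 1/(B_eff+1); with fewer than 10
  distinct label partitions a warning flags coarse p-values.
- With very small chips the specificity null (random subsets of a small
  pool) overlaps the mapped set heavily, deflating specificity scores.
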