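# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that a maintainer would otherwise
have to reverse-engineer from the code.

## Coordinates and data model

Variant positions are 1-based (VCF convention); every interval — arms,
masks, tracts, density windows — is 0-based half-open (BED convention). The
single conversion lives in `recsel.genome.pos1_to_index`; all membership
tests route through it, so a variant at 1-based position `start + 1` is the
first base inside an interval and one at `end + 1` is the first outside.

Panels are polarized on input: the ancestral allele comes from an INFO key
(default `AA`), sites where it equals ALT are flipped to derived
orientation, and sites where it matches neither allele, lacks the tag, or
is multi-allelic are dropped and counted in the read report. Ancestral
annotations are assumed to be reported on the reference strand; no
complementation is attempted. Genotypes must be phased (unphased
heterozygotes are an error naming the record; unphased homozygotes are
accepted since their haplotype assignment is unambiguous).

## Singleton catalog and filters

A singleton is a site with derived-allele count 1 within a dataset; a
private doubleton has count 2 with both copies in one individual. The gap
model treats both as a single mutational event at one position carried by
one individual, so they are pooled everywhere downstream.

Filters flag entries rather than delete them (`retained`, `reason`), so
catalog cardinality is conserved and provenance auditable.

* **Exclusion mask** — BED intervals (centromere-like unreliable regions);
  half-open membership.
* **Density filter** — windows of 20 kbp tiling each chromosome from 0 with
  a 10-kbp step (half-overlapping; the code enforces window = 2 × step).
  Counts of retained entries are accumulated per dataset over all windows
  genome-wide, *including empty windows* that intersect analyzable arms;
  whether empty windows enter the mean/SD and whether windows tile per
  chromosome or per arm were open choices, fixed here as documented
  defaults. The threshold is mean + 4 SD (population SD), interpreted
  one-sided: only excess density marks miscalled regions. An entry covered
  by *any* over-threshold window is removed — with half-overlap each point
  lies in two windows, and the conservative any-window rule is used. Under
  a uniform Poisson placement the removal fraction is below 1e-3 (verified
  by test).

## Gap likelihood and the raw selection score

For a test variant and an individual with `n_d ∈ {0,1,2}` derived
haplotypes, let g be the sum of the distances to the nearest retained
singletons carried by that individual strictly before and strictly after
the variant, within the same chromosome arm. Each haplotype is modeled as
an independent homogeneous Poisson process, so the per-side nearest
distance is exponential with the summed rate
λ(i) = (2 − n_d)·λ_a + n_d·λ_d and g ~ Gamma(shape 2, rate λ(i)). The
per-variant log-likelihood is Σ_i [2 log λ(i) − λ(i) g_i], maximized over
(λ_a, λ_d) > 0; the raw score log λ̂_a − log λ̂_d is positive when derived
haplotypes are singleton-poor, i.e. rose recently.

This likelihood deliberately replaces the original formulation in which
per-DAF-bin gamma shape parameters are calibrated against an explicit
demographic model: that calibration requires an external demographic fit
and is absorbed here by the DAF-bin standardization step, which removes
frequency-dependent location and scale from the raw scores. This is the
package's one substantive modeling simplification; its practical
consequence is that raw scores are comparable only after bin
standardization, never across frequency bins directly.

Numerical choices:

* The likelihood is concave in (λ_a, λ_d) (log of a positive linear form
  plus linear terms), so coordinate ascent with *exact* per-coordinate
  quadratic-root updates converges to the global maximum. Updates are
  vectorized across variants from per-class sufficient statistics (counts
  and gap sums for the three genotype classes). Convergence: |Δ log-lik| <
  1e-10, at most 200 iterations. Starting values are the homozygote closed
  forms λ̂ = 1/mean(g) (class rate 2λ), falling back to the global mean gap
  when a homozygote class is absent.
* λ̂ is capped to [1e-12, 1e12] per bp; a fit hitting a cap is skipped with
  reason `rate_cap` (this also covers boundary MLEs when one allele class
  has only heterozygous carriers).
* A variant needs ≥ 10 non-censored individuals carrying at least one
  ancestral haplotype and ≥ 10 carrying at least one derived haplotype
  (`min_class_count`); otherwise it is skipped with reason `class_count`.
* Individuals with no flanking singleton on either side within the arm are
  censored and dropped (no boundary imputation). Variants closer than one
  median total gap to an arm end are skipped (`arm_edge`): edge censoring
  there is asymmetric and would bias λ̂ upward on one class.

## Standardization, meta-analysis, significance

Raw scores are computed separately per chromosome arm and per dataset;
standardization pools arms genome-wide within a dataset. Bins partition
(0, 1): width 0.005 below DAF 0.1 and above 0.9, width 0.01 between;
half-open [lo, hi). The per-dataset DAF indexes the bin. Bins with fewer
than 20 scored variants are merged left-to-right with neighbors (a
trailing short group joins its predecessor). Within a merged group
z = (raw − mean)/SD with the population SD, so each group has mean 0 and
SD exactly 1.

Variants scored in *all* datasets are meta-analyzed with weights √n_i
(z_meta = Σ w_i z_i / √Σ w_i²), then the meta scores are re-standardized
genome-wide — a single mean/SD, not per bin, since the second
normalization is defined without bins — giving the final z and
P = 2·Φ(−|z|), flagged significant at P < 5×10⁻⁸.

## DAF heterogeneity

The index h = χ²/N on the subpopulation × allele table (Pearson, no
continuity correction; subpopulations with zero alleles dropped;
monomorphic tables defined as 0). Because the allele axis has one degree
of freedom, h is the squared Cramér V and lies in [0, 1]; it is invariant
under swapping the derived/ancestral labels of all subpopulations at once.

The empirical null for a focal variant is the set of h values of all other
variants whose pooled DAF lies within ± 0.005 of the focal pooled DAF
(pooled, because it is the only DAF defined for every cohort). A bin with
fewer than 100 variants widens symmetrically in 0.005 steps and the record
is flagged. The one-tailed P is the add-one exceedance
(1 + #{null ≥ h}) / (1 + |null|) — ties count against enrichment — and the
fold change is h / mean(null), undefined (reported missing) when the null
mean is 0.

## Introgression-tract rotation test

Chromosomes are concatenated in layout order into a circle of length L.
The observed statistic is the mean final z over variants inside the tract
set. Rotation j (j = 1..10,000) shifts every tract by j × 0.01% of L
modulo L, splitting tracts that wrap; variants never move, so the spatial
autocorrelation of the z field is preserved while tract flags shuffle. The
schedule is systematic — no randomness, bit-reproducible. Rotations
covering zero variants are excluded from the null and counted. The
two-sided P centers the observed statistic at the mean of the null means
(the natural center for the rotation family):
P = (1 + #{|m_j − μ| ≥ |m_obs − μ|}) / (1 + n_used). With the default
increment × iterations covering the full circle, the final rotation
coincides with the identity, so P is never exactly 0. Masked regions stay
in the coordinate system (tracts are rotated over them); compacting them
out is a documented alternative not enabled by default.

## Trait-set enrichment

Final z-scores are rank-normalized, z'_i = Φ⁻¹((r_i − 0.5)/M) with average
ranks for ties — exactly mean 0 (up to ties) and order-preserving. Trait
variants map to themselves when scored, otherwise to the scored variant
with maximal haplotype r² = D²/(p(1−p)q(1−q)) within 1 Mbp, kept only when
r² > 0.5; unmapped variants are dropped with a count, and variants landing
on the same proxy collapse to one (avoids double-counting a signal).
S = Σz'² is referred to χ² with k = |mapped set| degrees of freedom;
inflation S/k. The χ² reference assumes independence within a trait set —
violated under LD; results are reported as-is with this caveat, matching
the procedure being emulated. Bonferroni uses α/n_traits (0.05/103 ≈
4.9×10⁻⁴ for the 97 + 6 trait layout this mirrors); the sensitivity rerun
drops scored variants inside the genome-wide-significant selection loci,
recomputes the rank normalization on the remainder, and applies
Benjamini–Hochberg q-values.

## Synthetic data: what it emulates, what it does not

The generator (`recsel.simulate`) is a pure function of (config, seed) and
emulates exactly the statistical structure the estimators consume:

* **Panels** — three phased datasets (default sizes 1276/492/466, the
  emulated study's cohorts) of biallelic common sites with DAF drawn
  uniformly on (0.01, 0.99) and haplotypes assigned independently.
* **Singletons** — per-haplotype Poisson process at λ₀ = 1e-4 /bp/haplotype
  (nearest singleton ≈ 5 kbp per side per individual, a desk-scale analogue
  of high-depth WGS singleton density on a 10-Mbp toy genome). Within ± 50
  kbp of a selected locus, haplotypes carrying the derived core allele are
  thinned to ρλ₀, ρ ∈ (0, 1]. This haplotype-class rate drop is the exact
  generative counterpart of the Gamma(2) likelihood, so parameter recovery
  is unbiased by construction and the scan's calibration can be tested
  sharply — the point is to validate the statistics, not to re-create
  coalescent realism.
* **Regional structure** — Balding–Nichols: per-region frequency
  Beta(daf(1−F)/F, (1−daf)(1−F)/F) with drift F = 0.005 (the order of the
  between-cluster F_ST this emulates), counts binomial given 2 × region
  sizes; the seven region labels and proportions follow the emulated
  biobank's recruitment. Selection on regional structure is modeled as an
  inflated F (×10 by default) rather than explicit frequency trajectories —
  enough to power the heterogeneity test.
* **Tracts and trait sets** — uniform non-overlapping tracts; trait sets
  sampled from scored variants, with enriched sets drawing half their
  variants from selected-locus windows. An optional generator knob
  (`selected_ld_copies`) plants near-copies of a selected core haplotype
  inside its window (flip noise 2%), inducing the LD that proxy mapping
  and locus-level enrichment rely on.

Not emulated: coalescent genealogies, recombination, background LD outside
the explicit copy blocks, mutation-rate heterogeneity, variant-calling
error, and ascertainment. Passing tests therefore demonstrate correctness
and calibration of the statistics under their own model assumptions — not
robustness to the artifacts of real sequencing data.

## Test and validation scales

Problem sizes were chosen so the full suite exercises every claim at
useful power: null calibration on 3 × 200 samples with ≥ 2000 scored
variants (final z mean ≈ 0, SD ≈ 1 by construction; the informative check
is the 5% two-sided tail at |z| > 1.96); parameter recovery on 20
replicates of 3 × 500 samples with a ρ = 0.2, DAF 0.5 locus, requiring the
core variant to beat the 99.9th percentile of neutral scores in ≥ 19/20;
type-I error of both enrichment tests within 0.05 ± 0.015 over 1000 draws.
`scripts/acceptance.py` repeats these measurements from scratch (10
recovery replicates) plus the analytically recomputable quantities
(two-tailed P from the four reported meta z-scores; the 0.05/103
Bonferroni threshold).

## Known limitations

* The simplified likelihood has no demographic calibration; absolute raw
  scores are not comparable to implementations that calibrate per-bin gamma
  shapes against a population model, though post-standardization z-scores
  target the same null.
* The χ²_k trait reference ignores within-set LD (documented above).
* Precedence between conflicting ancestral-allele sources is unresolved
  upstream; the reader takes a single annotation key and drops
  inconsistent sites rather than guessing.
* Arm-edge handling (skip within one median gap) and minimum bin
  occupancies are pragmatic defaults; results near arm boundaries and in
  sparse frequency bins are correspondingly conservative.
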