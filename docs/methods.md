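# Methods

This note records the models, numerical choices and known limitations of
`ernet`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Element calling

The caller works on the merged (summed) strand-specific 5′-end track of
all libraries. A nonzero position is a strand-specific local maximum if
no position within the open, centred window (±150 bp for the default
300-bp window) has a higher count; equal counts are resolved toward the
leftmost position, which makes the scan deterministic and checkable
against a brute-force oracle. Peaks closer than 150 bp on one strand are
deduplicated greedily left to right, keeping the higher (leftmost on
ties). A plus-strand peak is paired with the highest unclaimed
minus-strand peak 50–250 bp upstream — the divergent geometry of
bidirectionally transcribed regulatory elements — with plus peaks
processed in descending height so that competing pairings resolve
deterministically. Emitted elements whose TSSs come within 150 bp of a
stronger element's TSS are dropped as ambiguous.

Choices the data do not dictate:

- **Peak height floor** (default 5 merged reads) suppresses singleton
  noise positions; the scan itself has no height requirement.
- **Quantification window** is the element span ±100 bp, inclusive of
  both endpoint bases. The flank absorbs TSS jitter without reaching a
  neighbour ≥150 bp away. RPM normalisation divides by the library's
  total read count (genome-wide), not the in-element total.

## Variability

For each element, technical dispersion is the set of absolute log₂
differences (pseudocount 1 RPM) between replicate libraries of the same
individual; biological-plus-technical dispersion is the same statistic
over pairs of different individuals. Each individual is represented by
one library (the first in design order). Representing replicated
individuals by their replicate mean instead would halve their technical
variance, shrink the between-individual deviations, and make the test
conservative — measurably biasing the π₀ estimate upward by ~0.07 on
null cohorts — so the single-library representation is used: under the
global null both deviation samples are then exchangeable and the
rank-sum p-values are uniform.

The one-sided Wilcoxon rank-sum test (H₁: between-individual >
between-replicate) is exact for ≤25 values per group without ties,
normal-approximated with tie correction otherwise; completely tied data
yields p = 1. Between-individual pairs are capped at a seeded subsample
of 2000 per element. π₀ is Storey's uniform-tail estimate
#{p > λ}/((1−λ)m) at λ = 0.5; q-values are the step-up Storey form, and
elements with q below the FDR threshold (default 0.2) are flagged
variable.

## Co-expression

Pearson correlation is computed over all library columns for
intrachromosomal pairs of variable elements within 5 Mb
(centre-to-centre, centres at span midpoints). Zero-variance rows are
excluded from pairing rather than emitting undefined values. Distance
bins are either fixed doubling edges (1, 2, 4 … 1024 kb) or equal-count
blocks of 1000 pairs sorted by distance, the final block dropped when
under 20% full. The per-bin statistic is an order statistic: the upper
5th percentile is the ⌈0.05 n⌉-th highest value (the 50th highest of
1000); median and lower tail are defined analogously, so the three
curves are ordered by construction.

The spurious-correlation null is fitted from seeded draws (with
replacement) of interchromosomal or >1 Mb pairs: a Gaussian with mean
fixed at 0 and sd equal to the sample sd, plus a recorded maximal QQ
deviation. Two-sided p-values for pairs come from this empirical null
(not the t-distribution), with Benjamini–Hochberg FDR.

Genotype independence: an element's local genotype is the set of SNPs
inside its span with minor-allele frequency above 0.05; elements with no
such SNP are genotype-independent by definition. A pair with local SNPs
on both sides is scored by the maximum absolute cross-correlation of the
0/1/2 genotype vectors; its association p is the minimum two-sided
Pearson p over the cross SNP pairs (t transform), BH-corrected across
pairs at FDR 0.1 for removal. The strict set additionally requires all
cross-correlations below 0.05.

mRNA integration selects one representative TSS per gene — annotated
TSSs within 250 bp of a promoter-class element, the one with the highest
strand-matched 5′ signal (±20 bp) winning, leftmost on ties — and
correlates element RPM (replicates collapsed by mean, per individual)
with gene expression for pairs within 1 Mb, genes filtered at mean
≥ 1 RPKM. Signed distance is negative when the element lies upstream of
the TSS in the gene's orientation.

## TF dependency (ΔAUC)

A site *intersects* a pair when it lies in the gap between the two
spans and *occupies* when it overlaps a span; because the spans abut the
gap, "overlaps the gap and neither span" is equivalent to containment in
the gap, which is how the count is computed (a site can never both
intersect and occupy the same pair). The interval index is a sorted
searchsorted scheme with an explicit correction for sites longer than
the gap, verified against a brute-force oracle.

Intersection grouping is ≥2 sites vs ≤1; occupancy is "either element
occupied". Each group is binned separately with the same pairs-per-bin;
AUC is the sum of per-bin percentile values at unit bin-index width
(so absolute ΔAUC values are implementation-scaled and only z-scores are
externally comparable), truncated to the smaller group's bin count.
ΔAUC = AUC(low/no-TF) − AUC(with-TF): positive for an insulating factor,
negative for an activating one. The result table also reports
effect = −ΔAUC for figure-facing sign conventions.

The null re-places sites uniformly per chromosome, lengths resampled
from the TF's own site-length distribution, for a grid of site counts;
per count, the ΔAUC sample's mean and sd are recorded (with a Shapiro
normality p) and interpolated linearly in log(count). z is the
standardised ΔAUC at the TF's actual site count, p the two-sided normal
tail, q BH across the analysed panel per mode. TF clustering uses
Ward linkage on sign(ΔAUC)·(−log₁₀ q) per mode, with q floored at 1e-10
so one extreme significance cannot dominate the Euclidean geometry.

## Contact integration

Per-pair contact is the single matrix value between the bins holding
the two element midpoints (same-bin pairs flagged and excluded from
between-bin analyses). Background is the seeded Monte-Carlo mean contact
between random bin pairs at the same bin distance with neither bin
overlapping an element, interpolated where a distance has no qualifying
bins. Subtraction happens on the linear scale before any log transform;
negative adjusted values stay in linear analyses but are flagged out of
log-scale ones. Contact decay curves and contact ΔAUC reuse the
co-expression binning and ΔAUC machinery unchanged. The cross-modality
comparison joins the two TF panels, reports Pearson and Spearman
correlations of ΔAUC per mode, and flags outliers by residual from a
robust Theil–Sen fit exceeding 2 MAD-standardised units — robust so that
a single discordant TF cannot mask itself by inflating an OLS residual
scale.

## Strand orientation

For each element, the nearest downstream neighbour forms an adjacent
pair and the second-nearest an interleaved pair, distance measured
between the facing TSSs (upstream plus to downstream minus) because the
250-bp minimum-distance exclusion exists to keep one read from counting
in both elements. Sense correlation is the mean of the two same-strand
correlations; convergent is r(A⁺, B⁻) (polymerases pointing at each
other), divergent r(A⁻, B⁺). The distance trend is an unweighted
k-nearest-neighbour local linear regression (k = 200): the window is the
contiguous block of k nearest points in sorted distance order and the
fit within it is ordinary least squares, so k = n reduces exactly to one
global regression, constants are reproduced exactly, and a noiseless
linear signal is recovered to machine precision. The orientation test is a
Welch two-sample t-test of convergent vs divergent correlations in a
distance window (default 500–1500 bp), with the paired t-test reported
alongside since both values come from the same pairs.

## Synthetic cohorts

The generator defines the study conditions for every test:

- **Design**: 75 libraries — 67 individuals, the first 8 with a
  replicate pair.
- **Landscape**: divergent TSS pairs with internal gaps uniform in
  50–250 bp, facing-TSS spacing ≥150 bp, a configurable clustered
  fraction with spacing in 250 bp–10 kb to populate the short-range
  analyses; deterministic per seed, infeasible packings rejected.
- **Expression**: per-individual latent log-activities are multivariate
  normal with correlation ρ(d) = ρ₀·e^(−d/λ_d) between same-chromosome
  elements (ρ₀ = 0.6, λ_d = 100 kb by default; 0 across chromosomes).
  Only variable elements receive biological variance. Defaults:
  biological log-sd ≈ 0.3 (bio_cv 0.31), technical log-sd ≈ 0.05, mean
  ≈ 500 expected reads per element per library with 0.5 log-sd
  heterogeneity. These keep the log-normal and Poisson attenuation of
  the linear-scale Pearson r well under the 0.05 recovery band while
  biological variance dominates technical for the variability test.
  Counts are Poisson-sampled per strand (per-element strand ratio drawn
  once in 0.35–0.65) and RPM-normalised by a planted library depth —
  normalising by the realised in-element sum would make rows
  compositionally anti-correlated, which is an artifact real libraries
  (whose depth is mostly outside elements) do not share. ρ₀e^(−d/λ) with
  ρ₀ < 1 is positive semidefinite by construction; TF modifiers can
  break that, in which case the matrix is repaired by eigenvalue
  clipping with a warning.
- **TF roles**: sites are placed uniformly by default and the planted
  correlation is then modified according to the *realised* annotation —
  insulator: ρ × 0.15 for pairs with ≥2 intersecting sites; activator:
  ρ → 1 − (1−ρ)(1−0.25) for occupied pairs; bivalent: both; null: no
  effect; discordant: activator on expression, insulator-damped on
  contacts. Uniform placement keeps the real site set exchangeable with
  the permutation null's shuffles, so z-scores calibrate exactly; an
  optional targeted fraction concentrates sites in gaps/spans at the
  cost of that exchangeability. The damping/boost magnitudes are free
  parameters (no quantitative effect size exists to emulate) chosen to
  be clearly recoverable at desk scale.
- **Contacts**: expected contact c₀(1 + d/d₀)^(−α) (α = 1, d₀ = 10 kb)
  times (1 + γ·ρ_pair) for bins holding an element pair (γ = 3),
  Poisson-sampled, symmetric.
- **Genotypes**: Hardy–Weinberg 0/1/2 at MAF uniform in the requested
  range; a linked fraction of variable elements forms pairs sharing one
  genotype vector through in-span SNPs, each member receiving an
  additive effect of 0.35 per standardised allele count on its latent
  activity.
- **Tracks**: reads multinomially assigned to (element, strand) cells
  proportional to the expression matrix, placed at the TSS with a
  geometric jitter (p = 0.5, capped at ±20 bp), plus an optional uniform
  background fraction.
- **Convergent cooperativity**: adjacent pairs with facing distance in
  250–1500 bp share a per-individual latent component (sd 0.35) on the
  facing strands only (A⁺ and B⁻).

What the generator does **not** emulate: mappability and sequence
composition, UMI/duplication structure, linkage disequilibrium beyond a
single shared SNP per planted pair, chromatin-state heterogeneity,
promoter/enhancer class differences (class labels are annotations, not
generative states), and Hi-C normalisation artefacts. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the assumed generative model, not robustness to those
real-data complications.

## Problem sizes and analysis parameters in the test suite

The suite runs cohorts of 300–5000 elements on 6–45 Mb genomes with
permutation budgets of 30–100 per grid point and 200 k null draws —
sizes chosen so the whole suite completes in a couple of minutes while
every recovery band retains comfortable margin. On desk-scale genomes
the element density per Mb is far above the real genome's, so the
shuffled-site grids are scaled to keep both label groups populated, and
occupancy-mode analyses use smaller bins (60 pairs, ≥2 bins) with the
median curve as their statistic — the median is markedly more sensitive
than the upper-5th percentile when the with-TF group is small. A
single bivalent TF cannot be fully powered in both of its arms at this
scale (a site count dense enough for occupancy saturates intersection),
so its activating arm is validated by sign rather than by |z| > 3; this
is a scale limitation, not a property of the statistic.

## Known limitations

- The caller's tie rules (leftmost wins) are one of several defensible
  conventions; calls at exactly tied heights can differ from other
  implementations.
- Absolute ΔAUC values depend on pairs-per-bin through the unit
  bin-index AUC width; only z-scores are comparable across settings.
- The permutation background assumes the analysed TF's sites are
  exchangeable with uniform placement conditional on count and length
  distribution; strong positional biases of real TF sites (e.g. promoter
  concentration) are absorbed into, not separated from, the reported z.
- Storey's π₀ at a single λ = 0.5 is slightly conservative when p-values
  near 0.5 still carry signal; no spline smoothing is applied.
- The genotype filter tests marginal SNP-pair correlation only; it does
  not model haplotype structure.
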