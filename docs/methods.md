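# Methods

This package re-implements, as tested reusable components, the
computational analyses used to study how loss of LINC-complex function
(the SUN-domain protein koi in *Drosophila* larval muscle) shifts
chromatin toward a repressed state: differential DamID occupancy
statistics, a gene-proximity Monte-Carlo test, 3D nuclear image
quantification with hierarchical group comparison, and a coarse-grained
polymer model of H3K27me3–lamina tethering.  Seeded synthetic-data
generators stand in for the raw experimental data, so every stage is
testable end to end with known ground truth.

## Coarse-grained genome

The 176.2 Mbp fly genome is discretized at 5 kbp per bead (bead
diameter σ = 30 nm), giving N = 35,240 beads split into four equal
chains.  Each chain carries a single contiguous pericentromeric
heterochromatin (PCH) block of 30% of its beads, centered at the chain
midpoint (the position is a modelling choice — the data constrain only
the fraction; a chain-end placement is available).  H3K27me3 domains
are laid down as non-overlapping patches with lengths drawn from an
exponential distribution of mean 17 beads (85 kbp), discretized by
rounding with a one-bead floor, until 40% of the genome is flagged.

Two numerical points matter here:

- **Rejection scheme.** A proposed patch is rejected if it would
  overlap an existing patch or cross a chromosome boundary.  If the
  whole (length, position) proposal were redrawn on rejection, long
  patches would be selectively suppressed and the realized mean length
  falls to ≈13 beads at 40% coverage.  The generator therefore
  resamples only the *position* for a drawn length, which preserves
  the exponential's mean: over 50 seeded full-genome runs the pooled
  generated-patch mean is ≈17.0 beads and coverage is 40.0–40.1%
  (generation stops the first time the target is reached, so the
  overshoot is bounded by one patch length).
- **Coverage mode.** The default targets the 40% global coverage
  uniformly along the genome.  An optional per-compartment mode
  instead covers 22% of euchromatin and 77.5% of PCH (the midpoint of
  the 75–80% range); these compose to ≈38.7% globally, not exactly
  40% — a documented discrepancy between the two parameterizations.

## Polymer model

Chromosomes are bead-spring chains (harmonic springs, k = 100 kBT/σ²,
rest length σ) confined to a sphere whose radius R = (N/8φ)^{1/3} sets
a chromatin volume fraction φ = 0.15.  The surface is tiled with fixed
lamina beads on a Fibonacci lattice at ≈1σ spacing.  Pairwise
interactions are truncated, energy-shifted Lennard-Jones potentials
(cutoff 2.5σ): ε_HH = 0.5 kBT between heterochromatin beads (PCH and
H3K27me3 alike), ε_EE = 0.35 kBT between euchromatin beads, and
ε = 0.3 kBT — the poor-solvent collapse threshold — for cross pairs,
so that both chromatin types are self-attractive and phase separate
from the nucleoplasm with heterochromatin the denser phase.  An
H3K27me3 bead within 1.5σ of a lamina bead forms a harmonic bond
(stiffness K, rest length σ) to the nearest one; the bond breaks when
stretched beyond 2.5σ; each chromatin bead holds at most one bond
while lamina beads may host several.  Strong (K = 10 kBT/σ²) versus
weak (K = 1.5 kBT/σ²) tethering are the two regimes compared.

Dynamics are overdamped (Brownian) Euler–Maruyama with kBT = 1, γ = 1:
the simplest scheme with the correct equilibrium statistics, which is
what the model's claims concern.  The default timestep is Δt = 0.002τ:
the stiffest backbone chain mode has effective rate 4k/γ, and explicit
Euler needs 4kΔt < 2, so the conventional 0.01τ would be unstable at
k = 100.  Other numerical choices: pair forces are capped at 100
kBT/σ per pair (prevents blow-up when initial configurations overlap);
the confining wall is a hard radial reflection (an ideal gas then
samples the sphere uniformly — a property the tests check); lamina
beads additionally repel all chromatin through a purely repulsive WCA
contact; the bond registry is refreshed every 10 steps; neighbor
search uses linked-cell lists with half-cutoff cells (±2-cell scan),
capped at 128³ cells for very large radii.  Initial configurations are
confined random walks relaxed athermally for 500 small steps.
Trajectories are bit-for-bit reproducible given a seed.

## Simulation readouts

H3K27me3 clusters are connected components of the contact graph on
flagged beads (edge when closer than 1.5σ, the first-neighbor contact
distance; 2.5σ, the interaction range, is available).  "In the
nucleoplasm" has three interpretations, all implemented:

- `unbonded` (default): drop clusters containing any currently
  lamina-bonded bead;
- `radial`: drop clusters whose center of mass lies beyond 0.8 R;
- `detached`: remove the lamina-bonded beads first and cluster the
  remaining, detached H3K27me3 material.

At full scale the first definition matches the intuition of discrete
clusters that either sit at the lamina or diffuse freely.  At the
reduced system sizes used for testing (hundreds to a few thousand
beads), heterochromatin coarsens into a single condensed domain under
*both* tether strengths — the domain spans a large fraction of the
nucleus, almost always contains at least one bonded bead, and its
center of mass is never peripheral — so the first two definitions
become degenerate and discriminate nothing.  The `detached` definition
recovers the intended physics at reduced size: under strong tethering
most H3K27me3 is bonded at the wall and the detached remainder is
fragmented (mean cluster size ≈6 beads at N = 500), while under weak
tethering the detached material is the condensed domain itself (mean
≈27 beads).  The headline comparison therefore uses `detached`; the
per-frame mean counts frames without any nucleoplasmic cluster as zero
mass.

Radial profiles are bead counts in equal-thickness concentric shells
normalized by the subset's whole-sphere mean density.  At small R the
outermost of 10 shells is sterically inaccessible (wall plus lamina
contact exclude bead centers from roughly the outer σ), so reduced-size
comparisons use 5 shells.

Tether strengths are compared by pooling per-frame mean nucleoplasmic
cluster sizes after a 50% burn-in and applying a one-sided
Mann-Whitney test; the test suite additionally compares seed-level
means.  The reduced configuration used by the tests is N = 500 beads,
3×10⁴ steps, 5 seeds per K — the direction (larger nucleoplasmic
clusters and lower outermost-shell H3K27me3 density at K = 1.5) is
fully separated across seeds at this size.

## DamID differential occupancy

Input is a per-gene table of log2(Dam-fusion/Dam-only) occupancy
ratios, three replicates per condition, with an upstream per-gene FDR
and GATC-site count (raw-read processing is out of scope).  Genes are
filtered at FDR < 0.05 and GATC sites > 1 (both strict).  Each gene is
a 2D point (mean control, mean mutant occupancy); the regression line
is the major principal axis of the centered cloud, and the signed
perpendicular residual — oriented so mutant-enriched genes are
positive — is standardized (sample SD) into z_pca.  Genes with
|z| > 1.96 are significant, direction "increased" or "decreased" in
the mutant; on null data ≈5% of genes exceed the threshold by
construction.  One caveat the tests encode explicitly: when spiked
true hits are present they inflate the residual SD, so the realized
false-discovery proportion of calls is higher than a naive 5%/2
intuition suggests; a Gaussian-mixture calculation predicts the
operating point, and the tests assert agreement with it rather than an
optimistic constant.

Group overlap is reported as the Jaccard index in percent (min-set
denominator available).  Fold-change clustering uses k-means with the
number of clusters chosen by the Gap statistic (uniform-box reference,
B = 50, one-standard-error rule, k ≤ 6); missing entries are imputed
as zero fold change.

The proximity test asks whether hit genes cluster along chromosomes:
the statistic is the number of hit genes whose nearest other hit gene
lies within 10 kbp, with distance the gap between gene bodies (zero if
overlapping; midpoint distance is an option).  The null redraws the
same number of genes uniformly without replacement from the annotation
restricted to the four large autosome arms, 1000 times, and
p = (NGE + 1)/(Nruns + 1).  Because the count statistic is heavily
tied for small hit sets, null p-values are valid but conservative
(super-uniform); approximate uniformity on the support holds once the
hit set is large enough for rich count support, and that is how the
property is tested.

## 3D nuclear image quantification

Nuclei are segmented from the DNA channel: Gaussian denoising (σ = 1
voxel), global Otsu threshold, 3D connected components, discarding
components touching the stack boundary or smaller than 20 µm³.  All
intensity statistics read only voxels inside the mask, so cytoplasmic
background cannot leak into mean nuclear intensities.  Puncta are
segmented per nucleus by subtracting the within-mask median (mode
available) as background, Otsu-thresholding the clipped residual
inside the mask, and filtering 3D components below 0.01 µm³.  Radial
profiles use the Euclidean distance transform (in µm, respecting voxel
anisotropy) from the nuclear border, split into equal-distance shells
from periphery to center, each shell's mean intensity divided by the
mean of a cytoplasmic reference shell (a ring dilated 3–6 voxels
outside the mask, excluding other nuclei).

Genotypes are compared with a linear mixed model: the chosen measure
on genotype as fixed effect with random intercepts for larva and for
muscle nested in larva (falling back to larva-only, flagged, if the
nested fit does not converge), optionally with log10(volume) and its
genotype interaction as fixed covariates.  The effect is reported as
percent change of the mutant relative to the fitted control mean.

## Synthetic data

Generators are pure functions of (spec, seed) and emit ground truth
sufficient to recover every latent quantity.

*DamID tables*: gene intervals are placed without overlap by the
uniform-spacings construction on four dm6-sized arms; baselines are
N(0, 1) in log2 units; replicates add N(0, 0.2) noise; true hits (50
of 5000 by default) add +1.5 log2 units in the mutant; a clustered
mode selects true hits as adjacent gene pairs closer than 10 kbp so
the proximity test has signal by construction.

*Nucleus cohorts*: 5 larvae × 3 muscles × 10 nuclei per genotype,
mirroring the study's cohort sizes.  Intensities carry multiplicative
log-normal random factors (coefficients of variation: larva 0.10,
muscle 0.08, nucleus 0.15 — chosen as typical between-animal and
between-cell variability for quantitative immunofluorescence), so
percent effects compose multiplicatively, matching how effects are
reported against control.  Each nucleus is an ellipsoid (radius
3.0–4.2 µm with ±8% per-axis eccentricity) rendered into its own
48³-voxel stack at 0.27 µm isotropic resolution, with a dimmer
cytoplasmic shell, optional peripheral chromatin rim, Gaussian read
noise (5% of the base intensity) and optional Poisson noise.  Puncta
are non-overlapping bright spheres with a Gaussian edge of σ = 0.08 µm
(a confocal-like point-spread blur) and log-normal volumes around
0.3 µm³; the half-height isosurface of such a punctum encloses exactly
its nominal volume, which makes the measured volume insensitive to the
exact threshold the segmentation lands on — with pure Gaussian blobs
the Otsu level is intensity-histogram-dependent and distorts recovered
volume *ratios* nonlinearly.  A puncta-study preset uses finer voxels
(0.125 µm, 72³) and 12 puncta per nucleus so the 0.01 µm³ filter scale
is well resolved.

What the generators do not emulate: realistic chromocenter texture,
anisotropic PSFs, spectral bleed-through, segmentation-adversarial
touching nuclei, and spatially correlated noise.  Recovery tests
therefore demonstrate that the pipeline is unbiased and correctly
calibrated under the stated generative model, not that it is robust to
every real-microscopy artifact.

## Problem sizes and recovery protocols

Effect-size recovery runs the full render → segment → quantify →
mixed-model pipeline on cohorts whose generator effects are the
published values (+43% H3K27me3, +82% H3K9me3, −37% H3K9ac, +45%
H3K27me3 under conditional knockdown, +149% punctum volume) and asks
that the median recovered effect over a 50-seed sweep (8 seeds in the
test suite) fall within ±25% relative of the injected value.  The
polymer-model comparison in the test suite uses N = 500 beads and
3×10⁴ steps per run; full-genome runs (N = 35,240) are supported by the
same engine but are not executed in the tests.

## Known limitations

- The deposited per-gene DamID tables are not redistributable here;
  hit calling on them (published counts 148/173/206) runs only when a
  user downloads the deposit to `data/mendeley/`.
- The polymer model's reduced-size behaviour over-coarsens
  heterochromatin into a single domain; only the `detached` cluster
  readout is meaningful there (see above).
- The mixed model fits raw intensities while the generator's random
  effects are multiplicative; at the simulated coefficients of
  variation (≤0.15) the induced bias is negligible against the ±25%
  recovery band.
- Bond formation/breaking is applied every 10 steps rather than every
  step; at the default timestep beads move ≪ 0.5σ between refreshes.
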