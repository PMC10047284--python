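"""Seeded generators for every input the analysis stages consume.

Two families:

- DamID: per-gene occupancy tables with replicate structure, a known
  minority of truly differential genes (optionally clustered along the
  genome), plus BED annotations.
- Microscopy: cohorts of 3D two-channel nucleus stacks with a
  larva -> muscle -> nucleus random-effect hierarchy of intensities,
  bright sub-nuclear puncta, optional peripheral chromatin bias and
  genotype effect sizes, with full ground truth.

Every generator is a pure function of (spec, seed).  Hierarchical
factors are log-normal (mean 1) so intensities stay positive and
percent effects are multiplicative, matching how effects are reported
as "% increase" relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .imaging import NucleusImage, NucleusQuant

#: approximate dm6 arm lengths (bp) for the four large autosome arms
DM6_ARM_LENGTHS = {
    "chr2L": 23_510_000,
    "chr2R": 25_290_000,
    "chr3L": 28_110_000,
    "chr3R": 32_080_000,
}


# ---------------------------------------------------------------------------
# DamID
# ---------------------------------------------------------------------------


@dataclass
class SynthDamidSpec:
    """Generator settings for a replicate-structured occupancy table."""

    n_genes: int = 5000
    n_true_hits: int = 50
    effect_size: float = 1.5  # log2 units added to mutant occupancy of true hits
    replicate_sd: float = 0.2  # log2 units
    baseline_sd: float = 1.0  # spread of per-gene baselines (log2)
    n_replicates: int = 3
    fdr_model: str | Callable = "uniform_pass"
    gatc_range: tuple[int, int] = (2, 20)
    chrom_lengths: dict = field(default_factory=lambda: dict(DM6_ARM_LENGTHS))
    clustering: Literal["none", "clustered"] = "none"
    clustering_window: int = 10_000
    mean_gene_length: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_true_hits > self.n_genes:
            raise ValueError("n_true_hits cannot exceed n_genes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


def gen_annotation(
    chrom_lengths: dict,
    n_genes: int,
    seed: int,
    mean_gene_length: float = 2000.0,
) -> pd.DataFrame:
    """Non-overlapping gene intervals, uniformly placed, as sorted BED6.

    Genes are apportioned to chromosomes proportionally to length;
    within a chromosome, gene starts are drawn by the uniform-spacings
    construction, which guarantees non-overlap.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    counts = _largest_remainder(
        np.array([chrom_lengths[c] / total for c in chroms]), n_genes
    )
    rows = []
    gi = 0
    for chrom, m in zip(chroms, counts):
        L = chrom_lengths[chrom]
        if m == 0:
            continue
        lengths = np.maximum(
            200, rng.lognormal(np.log(mean_gene_length) - 0.125, 0.5, m)
        ).astype(np.int64)
        free = L - lengths.sum()
        if free <= 0:
            raise ValueError(f"gene density infeasible on {chrom}")
        gaps = np.sort(rng.uniform(0, free, m)).astype(np.int64)
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for s, ln in zip(starts, lengths):
            rows.append((chrom, int(s), int(s + ln), f"g{gi:05d}", 0, "+"))
            gi += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    scaled = fracs / fracs.sum() * total
    out = np.floor(scaled).astype(int)
    order = np.argsort(-(scaled - out))
    out[order[: total - out.sum()]] += 1
    return out


def _draw_fdr(model, rng: np.random.Generator, truth: np.ndarray) -> np.ndarray:
    if callable(model):
        return model(rng, truth)
    if model == "uniform_pass":
        # all genes pass the FDR < 0.05 filter
        return rng.uniform(0.0, 0.045, len(truth))
    if model == "informative":
        fdr = rng.uniform(0.0, 0.2, len(truth))
        fdr[truth] = rng.uniform(0.0, 0.01, truth.sum())
        return fdr
    raise ValueError(f"unknown fdr_model {model!r}")


def gen_damid_table(
    spec: SynthDamidSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an occupancy table plus its ground truth.

    Control replicates are Normal(baseline, replicate_sd) in log2
    units; mutant replicates add ``effect_size`` for true hits.  With
    ``clustering="clustered"``, true hits are chosen as adjacent gene
    pairs whose genomic gap is below ``clustering_window``, so the
    proximity test has signal by construction.

    Returns ``(table, truth)`` where truth carries gene_id and
    ``true_hit``.
    """
    rng = np.random.default_rng(seed)
    ann = gen_annotation(
        spec.chrom_lengths, spec.n_genes, int(rng.integers(2**31 - 1)),
        spec.mean_gene_length,
    )
    n = len(ann)
    truth = np.zeros(n, dtype=bool)
    if spec.clustering == "clustered":
        gaps = np.full(n - 1, np.iinfo(np.int64).max)
        same = ann["chrom"].to_numpy()[1:] == ann["chrom"].to_numpy()[:-1]
        g = ann["start"].to_numpy()[1:] - ann["end"].to_numpy()[:-1]
        gaps[same] = g[same]
        close = np.flatnonzero(gaps < spec.clustering_window)
        rng.shuffle(close)
        picked: list[int] = []
        used = set()
        for i in close:
            if i in used or i + 1 in used:
                continue
            picked += [i, i + 1]
            used |= {i - 1, i, i + 1, i + 2}
            if len(picked) >= spec.n_true_hits:
                break
        if len(picked) < spec.n_true_hits:
            raise ValueError(
                "not enough close gene pairs for the requested clustered hits; "
                "increase gene density or the clustering window"
            )
        truth[picked[: spec.n_true_hits]] = True
    elif spec.n_true_hits:
        truth[rng.choice(n, spec.n_true_hits, replace=False)] = True

    baseline = rng.normal(0.0, spec.baseline_sd, n)
    reps = {}
    for r in range(1, spec.n_replicates + 1):
        reps[f"occ_ctrl_rep{r}"] = baseline + rng.normal(0, spec.replicate_sd, n)
        mut_base = baseline + np.where(truth, spec.effect_size, 0.0)
        reps[f"occ_mut_rep{r}"] = mut_base + rng.normal(0, spec.replicate_sd, n)

    lo, hi = spec.gatc_range
    cols = (
        ["gene_id", "chrom", "start", "end"]
        + [f"occ_ctrl_rep{r}" for r in range(1, spec.n_replicates + 1)]
        + [f"occ_mut_rep{r}" for r in range(1, spec.n_replicates + 1)]
        + ["fdr", "n_gatc"]
    )
    table = pd.DataFrame(
        {
            "gene_id": ann["name"],
            "chrom": ann["chrom"],
            "start": ann["start"],
            "end": ann["end"],
            **reps,
            "fdr": _draw_fdr(spec.fdr_model, rng, truth),
            "n_gatc": rng.integers(lo, hi + 1, n),
        }
    )[cols]
    truth_df = pd.DataFrame({"gene_id": ann["name"], "true_hit": truth})
    return table, truth_df


# ---------------------------------------------------------------------------
# Microscopy cohorts
# ---------------------------------------------------------------------------


@dataclass
class SynthNucleiSpec:
    """Generator settings for a hierarchical cohort of nucleus stacks.

    Cohort sizes default to 5 larvae x 3 muscles x 10 nuclei per
    genotype; intensities carry multiplicative log-normal larva, muscle
    and nucleus factors (coefficients of variation ``larva_sd`` etc.).
    ``genotype_effect`` is the percent change of the mutant's mean mark
    intensity; ``puncta_volume_effect`` the percent change of the
    mutant's mean punctum volume; ``genotype_volume_effect`` the
    percent change of nuclear volume.
    """

    n_larvae: int = 5
    muscles_per_larva: int = 3
    nuclei_per_muscle: int = 10
    radius_um: tuple[float, float] = (3.0, 4.2)
    voxel_size: tuple[float, float, float] = (0.27, 0.27, 0.27)
    shape: tuple[int, int, int] = (48, 48, 48)
    base_intensity: float = 100.0
    dna_intensity: float = 150.0
    cyto_frac: float = 0.15
    genotype_effect: float = 0.0  # % change of mean mark intensity in mutant
    genotype_volume_effect: float = 0.0  # % change of nuclear volume in mutant
    larva_sd: float = 0.10
    muscle_sd: float = 0.08
    nucleus_sd: float = 0.15
    peripheral_bias: float = 0.0
    puncta_count_mean: float = 8.0
    punctum_volume_um3: float = 0.3
    punctum_volume_sigma: float = 0.35  # sd of log volume
    puncta_contrast: float = 1.5  # peak height as multiple of nuclear mean
    puncta_volume_effect: float = 0.0  # % change of punctum volume in mutant
    psf_sigma_um: float = 0.08  # optical blur applied to punctum edges
    noise_sd_frac: float = 0.05
    poisson_noise: bool = False
    genotypes: tuple[str, str] = ("control", "mutant")

    def __post_init__(self) -> None:
        for name in ("larva_sd", "muscle_sd", "nucleus_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.radius_um) <= 0:
            raise ValueError("radii must be positive")
        max_r = max(self.radius_um) * (1 + max(self.genotype_volume_effect, 0) / 100) ** (1 / 3)
        for dim, v in zip(self.shape, self.voxel_size):
            if dim * v < 2 * max_r * 1.15 + 2 * v:
                raise ValueError("voxel grid too small for the nuclear radius")


def puncta_study_spec(**overrides) -> SynthNucleiSpec:
    """Preset for puncta-volume studies: fewer nuclei, finer voxels so
    0.01-0.5 um^3 puncta are well resolved."""
    base = dict(
        n_larvae=3,
        muscles_per_larva=2,
        nuclei_per_muscle=3,
        radius_um=(2.6, 3.2),
        voxel_size=(0.125, 0.125, 0.125),
        shape=(72, 72, 72),
        puncta_count_mean=12.0,
        puncta_contrast=2.0,
        noise_sd_frac=0.03,
    )
    base.update(overrides)
    return SynthNucleiSpec(**base)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-1 log-normal factor with coefficient of variation ~ cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def gen_nuclei_cohort(
    spec: SynthNucleiSpec, seed: int, render: bool = True
) -> tuple[list[NucleusImage] | None, pd.DataFrame]:
    """Generate a two-genotype cohort of single-nucleus stacks.

    Each nucleus is an ellipsoid (randomized per-axis radii) rendered
    into its own stack: DNA channel with optional peripheral rim, mark
    channel with the hierarchical mean intensity, non-overlapping
    bright puncta (spheres with a PSF-like soft edge) and Gaussian
    (optionally Poisson) noise, embedded in a dimmer cytoplasmic
    shell.  With ``render=False`` only the ground-truth
    table of latent values is produced (fast path for statistical
    checks).
    """
    rng = np.random.default_rng(seed)
    images: list[NucleusImage] | None = [] if render else None
    rows = []
    vol_scale = (1.0 + spec.genotype_volume_effect / 100.0) ** (1.0 / 3.0)
    for genotype in spec.genotypes:
        g = 1.0 if genotype == spec.genotypes[0] else 1.0 + spec.genotype_effect / 100.0
        pv_scale = (
            1.0
            if genotype == spec.genotypes[0]
            else 1.0 + spec.puncta_volume_effect / 100.0
        )
        r_scale = 1.0 if genotype == spec.genotypes[0] else vol_scale
        for li in range(spec.n_larvae):
            fl = float(_lognormal_factor(rng, spec.larva_sd))
            larva = f"{genotype[:3]}_L{li + 1}"
            for mi in range(spec.muscles_per_larva):
                fm = float(_lognormal_factor(rng, spec.muscle_sd))
                muscle = f"{larva}_M{mi + 1}"
                for ni in range(spec.nuclei_per_muscle):
                    fn = float(_lognormal_factor(rng, spec.nucleus_sd))
                    mark_mean = spec.base_intensity * g * fl * fm * fn
                    r0 = rng.uniform(*spec.radius_um) * r_scale
                    radii = r0 * (1.0 + rng.uniform(-0.08, 0.08, 3))
                    n_drawn = int(rng.poisson(spec.puncta_count_mean))
                    pvols = (
                        rng.lognormal(
                            np.log(spec.punctum_volume_um3)
                            - 0.5 * spec.punctum_volume_sigma**2,
                            spec.punctum_volume_sigma,
                            n_drawn,
                        )
                        * pv_scale
                    )
                    centers, pradii, pvols = _place_puncta(rng, radii, pvols)
                    n_puncta = len(pvols)
                    row = {
                        "genotype": genotype,
                        "larva_id": larva,
                        "muscle_id": muscle,
                        "nucleus_id": f"{muscle}_N{ni + 1}",
                        "mark_mean": mark_mean,
                        "larva_factor": fl,
                        "muscle_factor": fm,
                        "nucleus_factor": fn,
                        "radius_z": radii[0],
                        "radius_y": radii[1],
                        "radius_x": radii[2],
                        "volume": 4.0 / 3.0 * np.pi * np.prod(radii),
                        "n_puncta_true": n_puncta,
                        "mean_punctum_volume_true": float(pvols.mean())
                        if n_puncta
                        else np.nan,
                    }
                    rows.append(row)
                    if render:
                        images.append(
                            _render_nucleus(
                                spec, rng, radii, mark_mean, centers, pradii, row
                            )
                        )
    return images, pd.DataFrame(rows)


def _place_puncta(
    rng: np.random.Generator, nuc_radii: np.ndarray, volumes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place puncta inside the (unit-normalized) nucleus without overlap.

    Positions are fractions of the nuclear radii, kept within 0.75 of
    the surface; puncta that cannot be placed after 200 attempts are
    dropped (and excluded from the ground truth).  Returns centers (as
    fractional offsets), radii (um) and the kept volumes.
    """
    order = np.argsort(-volumes)
    centers: list[np.ndarray] = []
    radii_p: list[float] = []
    vols: list[float] = []
    mean_nuc_r = float(np.mean(nuc_radii))
    for v in volumes[order]:
        r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        for _ in range(200):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            frac = 0.75 * rng.uniform() ** (1.0 / 3.0)
            c = u * frac  # fractional ellipsoid coordinates
            c_um = c * nuc_radii
            ok = all(
                np.linalg.norm(c_um - q * nuc_radii) > (r + rp + 0.25)
                for q, rp in zip(centers, radii_p)
            )
            if ok and (frac * mean_nuc_r + r) < 0.9 * mean_nuc_r:
                centers.append(c)
                radii_p.append(r)
                vols.append(float(v))
                break
    return np.array(centers), np.array(radii_p), np.array(vols)


def _render_nucleus(
    spec: SynthNucleiSpec,
    rng: np.random.Generator,
    radii: np.ndarray,
    mark_mean: float,
    punctum_centers: np.ndarray,
    punctum_radii: np.ndarray,
    meta: dict,
) -> NucleusImage:
    shape = spec.shape
    vz, vy, vx = spec.voxel_size
    center = np.array(
        [shape[0] * vz / 2, shape[1] * vy / 2, shape[2] * vx / 2]
    ) + rng.uniform(-0.3, 0.3, 3)
    z = ((np.arange(shape[0]) + 0.5) * vz).astype(np.float32)
    y = ((np.arange(shape[1]) + 0.5) * vy).astype(np.float32)
    x = ((np.arange(shape[2]) + 0.5) * vx).astype(np.float32)
    # separable squared ellipsoid coordinate, accumulated in float32
    az = ((z - center[0]) / radii[0]) ** 2
    ay = ((y - center[1]) / radii[1]) ** 2
    ax = ((x - center[2]) / radii[2]) ** 2
    rho2 = az[:, None, None] + ay[None, :, None] + ax[None, None, :]
    mask = rho2 <= 1.0
    cyto = (rho2 > 1.0) & (rho2 <= np.float32(1.35**2))

    dna = np.where(
        mask,
        np.float32(spec.dna_intensity)
        * (1.0 + np.float32(spec.peripheral_bias) * rho2),
        np.where(cyto, np.float32(0.1 * spec.dna_intensity), np.float32(0.0)),
    ).astype(np.float32)
    mark = np.where(
        mask,
        np.float32(mark_mean),
        np.where(cyto, np.float32(spec.cyto_frac * mark_mean), np.float32(0.0)),
    ).astype(np.float32)

    # puncta as uniform bright spheres with a ~1-voxel Gaussian (PSF-like)
    # edge: the half-height isosurface volume equals the nominal volume and
    # is insensitive to the exact segmentation threshold
    from scipy.special import erf

    s_psf = spec.psf_sigma_um
    for cfrac, r in zip(punctum_centers, punctum_radii):
        c = center + cfrac * radii
        ext = r + 3.0 * s_psf
        zi = slice(
            max(0, int((c[0] - ext) / vz)), min(shape[0], int((c[0] + ext) / vz) + 1)
        )
        yi = slice(
            max(0, int((c[1] - ext) / vy)), min(shape[1], int((c[1] + ext) / vy) + 1)
        )
        xi = slice(
            max(0, int((c[2] - ext) / vx)), min(shape[2], int((c[2] + ext) / vx) + 1)
        )
        d = np.sqrt(
            (z[zi, None, None] - c[0]) ** 2
            + (y[None, yi, None] - c[1]) ** 2
            + (x[None, None, xi] - c[2]) ** 2
        )
        profile = 0.5 * (1.0 - erf((d - r) / (np.sqrt(2.0) * s_psf)))
        mark[zi, yi, xi] += (spec.puncta_contrast * mark_mean * profile).astype(
            np.float32
        )

    if spec.noise_sd_frac > 0:
        noise_sd = np.float32(spec.noise_sd_frac * spec.base_intensity)
        dna += noise_sd * rng.standard_normal(shape, dtype=np.float32)
        mark += noise_sd * rng.standard_normal(shape, dtype=np.float32)
    np.clip(dna, 0, None, out=dna)
    np.clip(mark, 0, None, out=mark)
    if spec.poisson_noise:
        dna = rng.poisson(dna).astype(np.float32)
        mark = rng.poisson(mark).astype(np.float32)

    return NucleusImage(
        dna=dna,
        mark=mark,
        voxel_size=spec.voxel_size,
        metadata={
            "genotype": meta["genotype"],
            "larva_id": meta["larva_id"],
            "muscle_id": meta["muscle_id"],
            "nucleus_id": meta["nucleus_id"],
        },
    )


def quants_from_truth(truth: pd.DataFrame) -> list[NucleusQuant]:
    """Ground-truth latent values repackaged as per-nucleus quants.

    Lets the mixed-model stage be exercised on the exact latent
    hierarchy, bypassing rendering and segmentation."""
    out = []
    for _, r in truth.iterrows():
        out.append(
            NucleusQuant(
                volume=float(r["volume"]),
                mean_mark_intensity=float(r["mark_mean"]),
                total_dna_intensity=float(r["volume"]),
                genotype=r["genotype"],
                larva_id=r["larva_id"],
                muscle_id=r["muscle_id"],
                nucleus_id=r["nucleus_id"],
            )
        )
    return out


def write_cohort(images: list[NucleusImage], truth: pd.DataFrame, outdir) -> pd.DataFrame:
    """Write TIFF stacks plus a samples CSV; returns the samples table."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        name = f"{im.metadata['nucleus_id']}.tif"
        arr = np.stack([im.dna, im.mark])  # (channel, z, y, x)
        tifffile.imwrite(outdir / name, arr, metadata={"axes": "CZYX"})
        rows.append(
            {
                "file": name,
                "genotype": im.metadata["genotype"],
                "larva_id": im.metadata["larva_id"],
                "muscle_id": im.metadata["muscle_id"],
                "nucleus_id": im.metadata["nucleus_id"],
                "dna_channel": 0,
                "mark_channel": 1,
                "voxel_z": im.voxel_size[0],
                "voxel_y": im.voxel_size[1],
                "voxel_x": im.voxel_size[2],
            }
        )
    samples = pd.DataFrame(rows)
    samples.to_csv(outdir / "samples.csv", index=False)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    return samples


def read_cohort(samples_csv) -> list[NucleusImage]:
    """Load a cohort written by :func:`write_cohort`."""
    import tifffile
    from pathlib import Path

    samples = pd.read_csv(samples_csv)
    root = Path(samples_csv).parent
    images = []
    for _, r in samples.iterrows():
        arr = tifffile.imread(root / r["file"])
        images.append(
            NucleusImage(
                dna=arr[int(r["dna_channel"])],
                mark=arr[int(r["mark_channel"])],
                voxel_size=(r["voxel_z"], r["voxel_y"], r["voxel_x"]),
                metadata={
                    "genotype": r["genotype"],
                    "larva_id": r["larva_id"],
                    "muscle_id": r["muscle_id"],
                    "nucleus_id": r["nucleus_id"],
                },
            )
        )
    return images
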