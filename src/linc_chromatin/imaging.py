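"""3D nuclear image quantification.

Segments myonuclei from the DNA (Hoechst / histone reporter) channel in
3D, restricts all intensity measures to the nuclear mask (removing
cytoplasmic background from mean nuclear intensities), segments bright
sub-nuclear puncta after per-nucleus background subtraction with a
0.01 um^3 volume filter, computes periphery-to-center radial intensity
profiles, and compares genotypes with a linear mixed model (genotype as
fixed effect; larva, and muscle nested in larva, as random effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
import statsmodels.formula.api as smf


@dataclass
class NucleusImage:
    """A two-channel 3D stack (DNA + mark) with voxel-size metadata."""

    dna: np.ndarray  # (z, y, x)
    mark: np.ndarray  # (z, y, x)
    voxel_size: tuple[float, float, float]  # (z, y, x) in um
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dna.shape != self.mark.shape:
            raise ValueError("DNA and mark channels must have congruent shapes")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class Punctum:
    volume: float  # um^3
    mean_intensity: float


@dataclass
class NucleusQuant:
    """Per-nucleus measurements with hierarchy identifiers."""

    volume: float  # um^3
    mean_mark_intensity: float
    total_dna_intensity: float
    genotype: str = ""
    larva_id: str = ""
    muscle_id: str = ""
    nucleus_id: str = ""
    puncta: list[Punctum] = field(default_factory=list)
    radial_profile: np.ndarray | None = None

    @property
    def n_puncta(self) -> int:
        return len(self.puncta)

    @property
    def mean_punctum_volume(self) -> float | None:
        if not self.puncta:
            return None
        return float(np.mean([p.volume for p in self.puncta]))


def segment_nuclei(
    stack: NucleusImage,
    sigma: float = 1.0,
    min_nucleus_volume: float = 20.0,
    exclude_boundary: bool = True,
) -> list[np.ndarray]:
    """Segment nuclei from the DNA channel.

    Gaussian denoising (``sigma`` voxels) -> global Otsu threshold ->
    3D connected components; components touching the stack boundary or
    smaller than ``min_nucleus_volume`` (um^3) are discarded.  Returns
    disjoint boolean masks, largest first.
    """
    img = ndimage.gaussian_filter(stack.dna.astype(np.float32), sigma)
    if img.max() == img.min():
        return []
    bw = img > threshold_otsu(img)
    if not bw.any():
        return []
    lbl, n = cc_label(bw, return_num=True)
    masks = []
    for i in range(1, n + 1):
        mask = lbl == i
        if exclude_boundary and _touches_boundary(mask):
            continue
        vol = mask.sum() * stack.voxel_volume
        if vol < min_nucleus_volume:
            continue
        masks.append(mask)
    if not masks:
        warnings.warn("no nucleus survived segmentation filters", stacklevel=2)
    masks.sort(key=lambda m: -m.sum())
    return masks


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any()
        or mask[-1].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    )


def quantify_nucleus(mask: np.ndarray, stack: NucleusImage) -> NucleusQuant:
    """Volume, mean mark intensity and total DNA intensity over the mask.

    Only voxels inside the mask are read, so cytoplasmic background
    cannot leak into the mean nuclear intensity.
    """
    if not mask.any():
        raise ValueError("empty mask")
    md = stack.metadata
    return NucleusQuant(
        volume=float(mask.sum() * stack.voxel_volume),
        mean_mark_intensity=float(stack.mark[mask].mean()),
        total_dna_intensity=float(stack.dna[mask].sum()),
        genotype=str(md.get("genotype", "")),
        larva_id=str(md.get("larva_id", "")),
        muscle_id=str(md.get("muscle_id", "")),
        nucleus_id=str(md.get("nucleus_id", "")),
    )


def segment_puncta(
    mask: np.ndarray,
    mark: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_volume: float = 0.01,
    background: str = "median",
) -> list[Punctum]:
    """Segment bright puncta within one nucleus.

    The per-nucleus background (median of the mark intensity inside the
    mask, or the histogram mode with ``background="mode"``) is
    subtracted and clipped at zero, preserving only the bright puncta;
    an Otsu threshold on the within-mask residual then defines punctum
    voxels.  3D components below ``min_volume`` um^3 are filtered out.
    """
    if not mask.any():
        raise ValueError("empty mask")
    vals = mark[mask].astype(np.float64)
    if background == "median":
        bg = float(np.median(vals))
    elif background == "mode":
        hist, edges = np.histogram(vals, bins=64)
        bg = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    else:
        raise ValueError("background must be 'median' or 'mode'")
    resid = np.where(mask, np.clip(mark - bg, 0.0, None), 0.0)
    inmask = resid[mask]
    if inmask.max() <= 0 or inmask.min() == inmask.max():
        return []
    thr = threshold_otsu(inmask)
    bw = resid > thr
    lbl, n = cc_label(bw, return_num=True)
    voxvol = float(np.prod(voxel_size))
    puncta = []
    for i in range(1, n + 1):
        pm = lbl == i
        vol = pm.sum() * voxvol
        if vol < min_volume:
            continue
        puncta.append(Punctum(volume=float(vol), mean_intensity=float(mark[pm].mean())))
    return puncta


def cytoplasm_reference(
    mask: np.ndarray,
    all_nuclei: list[np.ndarray] | None = None,
    inner_margin: int = 3,
    thickness: int = 3,
) -> np.ndarray:
    """A shell outside the nucleus used as the cytoplasmic reference:
    dilated ``inner_margin`` to ``inner_margin + thickness`` voxels
    beyond the mask, excluding any other nucleus."""
    inner = ndimage.binary_dilation(mask, iterations=inner_margin)
    outer = ndimage.binary_dilation(inner, iterations=thickness)
    ref = outer & ~inner
    if all_nuclei is not None:
        for other in all_nuclei:
            if other is not mask:
                ref &= ~ndimage.binary_dilation(other, iterations=1)
    return ref


def radial_distribution(
    mask: np.ndarray,
    channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    n_shells: int = 10,
    reference_region: np.ndarray | None = None,
) -> np.ndarray:
    """Periphery-to-center radial intensity profile.

    Consecutive radial shells are built from the Euclidean distance (in
    um, respecting voxel anisotropy) of each nuclear voxel to the
    nuclear border and split into ``n_shells`` equal-distance bins;
    shell 1 is the most peripheral.  Each shell's mean intensity is
    divided by the mean intensity of the cytoplasmic reference region.
    """
    if reference_region is None or not reference_region.any():
        raise ValueError("a non-empty cytoplasmic reference region is required")
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("mask too small for a radial profile")
    cyto = float(channel[reference_region].mean())
    if cyto == 0:
        raise ValueError("cytoplasmic reference has zero mean intensity")
    edges = np.linspace(0.0, dmax, n_shells + 1)
    profile = np.empty(n_shells)
    inside = dist > 0
    shell_idx = np.clip(np.digitize(dist[inside], edges) - 1, 0, n_shells - 1)
    vals = channel[inside].astype(np.float64)
    for s in range(n_shells):
        sel = shell_idx == s
        profile[s] = vals[sel].mean() / cyto if sel.any() else np.nan
    return profile


@dataclass
class GroupComparisonResult:
    """Mixed-model comparison of a per-nucleus measure between genotypes."""

    effect_pct: float
    p_value: float
    control: str
    treatment: str
    measure: str
    fallback_larva_only: bool
    model_result: object = field(repr=False, default=None)

    def summary(self):
        return self.model_result.summary()


def quants_to_dataframe(quants: list[NucleusQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        rows.append(
            {
                "genotype": q.genotype,
                "larva_id": q.larva_id,
                "muscle_id": q.muscle_id,
                "nucleus_id": q.nucleus_id,
                "volume": q.volume,
                "mean_mark_intensity": q.mean_mark_intensity,
                "total_dna_intensity": q.total_dna_intensity,
                "n_puncta": q.n_puncta,
                "mean_punctum_volume": q.mean_punctum_volume,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    quants: list[NucleusQuant] | pd.DataFrame,
    measure: str = "mean_mark_intensity",
    control: str = "control",
    log_volume_covariate: bool = False,
    volume_interaction: bool = False,
) -> GroupComparisonResult:
    """Linear mixed model: measure ~ genotype, random intercepts for
    larva and for muscle nested within larva.

    With ``log_volume_covariate`` the model adds log10(nuclear volume)
    (and optionally its genotype interaction) as fixed effects, for
    intensity-versus-volume comparisons.  The effect is reported as the
    percent change of the treatment group relative to the control group
    mean (evaluated at the mean covariate when one is present).  If the
    nested fit fails to converge the model falls back to a larva-only
    random intercept and flags it.
    """
    df = quants if isinstance(quants, pd.DataFrame) else quants_to_dataframe(quants)
    df = df.dropna(subset=[measure]).copy()
    genos = sorted(df["genotype"].unique())
    if len(genos) != 2 or control not in genos:
        raise ValueError(f"need exactly 2 genotypes including {control!r}, got {genos}")
    treatment = [g for g in genos if g != control][0]
    if df.groupby("genotype")["larva_id"].nunique().min() < 2:
        raise ValueError("need >= 2 larvae per genotype")

    df["is_mut"] = (df["genotype"] == treatment).astype(float)
    terms = ["is_mut"]
    if log_volume_covariate:
        df["log_vol"] = np.log10(df["volume"])
        df["log_vol_c"] = df["log_vol"] - df["log_vol"].mean()
        terms.append("log_vol_c")
        if volume_interaction:
            terms.append("is_mut:log_vol_c")
    formula = f"{measure} ~ " + " + ".join(terms)

    def _fit(vc):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                df,
                groups=df["larva_id"],
                re_formula="1",
                vc_formula=vc,
            )
            return model.fit(reml=True)

    fallback = False
    try:
        res = _fit({"muscle": "0 + C(muscle_id)"})
        if not res.converged or not np.isfinite(res.bse["is_mut"]):
            raise ValueError("nested fit did not converge")
    except Exception:
        fallback = True
        res = _fit(None)

    beta = float(res.params["is_mut"])
    control_mean = float(res.params["Intercept"])
    if control_mean == 0:
        raise ValueError("control mean is zero; percent effect undefined")
    effect_pct = 100.0 * beta / control_mean
    p = float(res.pvalues["is_mut"])
    return GroupComparisonResult(
        effect_pct=effect_pct,
        p_value=p,
        control=control,
        treatment=treatment,
        measure=measure,
        fallback_larva_only=fallback,
        model_result=res,
    )


def quantify_cohort(
    images: list[NucleusImage],
    sigma: float = 1.0,
    min_nucleus_volume: float = 20.0,
    with_puncta: bool = False,
    min_punctum_volume: float = 0.01,
) -> list[NucleusQuant]:
    """Segment and quantify every nucleus of a cohort of stacks.

    Runs the full per-stack pipeline (segment_nuclei ->
    quantify_nucleus, optionally segment_puncta) and pools the results.
    """
    quants: list[NucleusQuant] = []
    for im in images:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = segment_nuclei(im, sigma=sigma, min_nucleus_volume=min_nucleus_volume)
        for j, mask in enumerate(masks):
            q = quantify_nucleus(mask, im)
            if not q.nucleus_id:
                q.nucleus_id = f"n{j}"
            if with_puncta:
                q.puncta = segment_puncta(
                    mask, im.mark, im.voxel_size, min_volume=min_punctum_volume
                )
            quants.append(q)
    return quants
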