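"""DamID differential-occupancy statistics.

Works on per-gene occupancy tables: log2(Dam-fusion / Dam-only) ratios
per replicate for a control and a mutant condition, with an upstream
per-gene FDR and GATC-site count.  Provides the filtering rules, the
PCA-regression z-score hit caller (a gene is a hit when its
perpendicular deviation from the major axis of the control-vs-mutant
scatter exceeds 1.96 standard deviations), set-overlap summaries,
k-means/Gap-statistic clustering of fold changes, and a Monte-Carlo
test for genomic clustering of hit genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

#: canonical occupancy-table columns
OCC_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "occ_ctrl_rep1",
    "occ_ctrl_rep2",
    "occ_ctrl_rep3",
    "occ_mut_rep1",
    "occ_mut_rep2",
    "occ_mut_rep3",
    "fdr",
    "n_gatc",
]

DM6_ARMS = ("chr2L", "chr2R", "chr3L", "chr3R")


def read_occupancy_table(path) -> pd.DataFrame:
    """Read a per-gene occupancy TSV and validate its schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occupancy table missing columns: {missing}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 annotation (0-based half-open intervals)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        comment="#",
    )
    return df


def filter_genes(
    table: pd.DataFrame, fdr_threshold: float = 0.05, gatc_min: int = 1
) -> pd.DataFrame:
    """Retain genes with fdr < threshold and n_gatc > minimum (both strict)."""
    out = table[(table["fdr"] < fdr_threshold) & (table["n_gatc"] > gatc_min)].copy()
    if len(out) == 0 and len(table) > 0:
        warnings.warn("no genes survive FDR/GATC filtering", stacklevel=2)
    return out


def _replicate_means(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ctrl = table[[c for c in table.columns if c.startswith("occ_ctrl_")]].mean(axis=1)
    mut = table[[c for c in table.columns if c.startswith("occ_mut_")]].mean(axis=1)
    return ctrl.to_numpy(), mut.to_numpy()


def pca_regression_hits(
    table: pd.DataFrame, z_threshold: float = 1.96
) -> pd.DataFrame:
    """PCA-regression z-scores for differential occupancy.

    Each gene becomes a 2D point (mean control occupancy, mean mutant
    occupancy).  The regression line is the major principal axis of the
    centered cloud; the signed perpendicular residual (projection onto
    the minor axis, oriented so mutant-enriched genes are positive) is
    standardized into a z-score.  Genes with |z| above the two-tailed
    threshold are flagged significant, with direction "increased" or
    "decreased" (occupancy in the mutant).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 genes for PCA regression")
    x, y = _replicate_means(table)
    pts = np.column_stack([x, y])
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if evals[1] <= 0:
        raise ValueError("degenerate point cloud: zero variance")
    minor = evecs[:, 0]
    # orient the minor axis toward mutant enrichment (less ctrl, more mut)
    if minor @ np.array([-1.0, 1.0]) < 0:
        minor = -minor
    resid = centered @ minor
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate point cloud: zero residual variance")
    z = resid / sd

    out = table.copy()
    out["z_pca"] = z
    out["direction"] = np.where(z > 0, "increased", "decreased")
    out["significant"] = np.abs(z) > z_threshold
    return out


def group_overlap(
    hits_a, hits_b, denominator: str = "union"
) -> float:
    """Percent overlap of two hit-gene sets.

    ``denominator="union"`` gives the Jaccard index as a percentage;
    ``"min"`` divides by the smaller set instead.
    """
    a, b = set(hits_a), set(hits_b)
    inter = len(a & b)
    if denominator == "union":
        denom = len(a | b)
    elif denominator == "min":
        denom = min(len(a), len(b))
    else:
        raise ValueError("denominator must be 'union' or 'min'")
    return 100.0 * inter / denom if denom else 0.0


@dataclass
class GapClusteringResult:
    labels: np.ndarray
    k: int
    gap: np.ndarray  # Gap(k) for k = 1..k_max
    sk: np.ndarray  # reference-spread term
    kept_index: np.ndarray  # row index into the input after dropping all-NaN rows


def cluster_fold_changes(
    fold_changes: pd.DataFrame | np.ndarray,
    k_max: int = 6,
    n_refs: int = 50,
    seed: int = 0,
) -> GapClusteringResult:
    """K-means clustering of per-gene fold changes with the number of
    clusters chosen by the Gap statistic.

    Missing entries (genes not scored for a factor) are imputed as zero
    fold change; all-missing rows are dropped with a warning.  The Gap
    reference is uniform over the data's bounding box (B = ``n_refs``),
    and k is the smallest value satisfying the one-standard-error rule
    Gap(k) >= Gap(k+1) - s(k+1).
    """
    X = np.asarray(fold_changes, dtype=float)
    if X.ndim != 2:
        raise ValueError("fold_changes must be 2-dimensional")
    all_nan = np.all(np.isnan(X), axis=1)
    if all_nan.any():
        warnings.warn(f"dropping {all_nan.sum()} all-missing rows", stacklevel=2)
    kept = np.flatnonzero(~all_nan)
    X = np.nan_to_num(X[kept], nan=0.0)
    if len(X) < 2 * k_max:
        raise ValueError("need at least 2*k_max genes")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int, rs: int) -> tuple[float, np.ndarray]:
        km = KMeans(n_clusters=k, n_init=10, random_state=rs).fit(data)
        return np.log(max(km.inertia_, 1e-12)), km.labels_

    ks = np.arange(1, k_max + 1)
    gap = np.empty(k_max)
    sk = np.empty(k_max)
    labels_by_k = {}
    base_rs = int(rng.integers(2**31 - 1))
    for i, k in enumerate(ks):
        lw, labels_by_k[k] = log_wk(X, k, base_rs)
        ref_lw = np.empty(n_refs)
        for b in range(n_refs):
            ref = rng.uniform(lo, hi, size=X.shape)
            ref_lw[b], _ = log_wk(ref, k, base_rs)
        gap[i] = ref_lw.mean() - lw
        sk[i] = ref_lw.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)

    chosen = k_max
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            chosen = int(ks[i])
            break
    return GapClusteringResult(
        labels=labels_by_k[chosen], k=chosen, gap=gap, sk=sk, kept_index=kept
    )


@dataclass
class ProximityTestResult:
    observed_count: int
    null_counts: np.ndarray
    null_median: float
    p_value: float
    n_hits: int
    nruns: int


def _count_close_genes(
    chrom_codes: np.ndarray, starts: np.ndarray, ends: np.ndarray, window: int
) -> int:
    """Number of genes whose nearest other gene (interval gap) lies
    within ``window`` bp.  Overlapping genes have gap 0."""
    count = 0
    order = np.argsort(chrom_codes, kind="stable")
    cc = chrom_codes[order]
    s = starts[order]
    e = ends[order]
    boundaries = np.flatnonzero(np.diff(cc)) + 1
    blocks = np.split(np.arange(len(cc)), boundaries)
    for blk in blocks:
        m = len(blk)
        if m < 2:
            continue
        bs, be = s[blk], e[blk]
        gap = np.maximum(
            0, np.maximum(bs[:, None] - be[None, :], bs[None, :] - be[:, None])
        )
        np.fill_diagonal(gap, np.iinfo(np.int64).max)
        count += int((gap.min(axis=1) < window).sum())
    return count


def proximity_mc_test(
    hits,
    annotation: pd.DataFrame,
    window: int = 10_000,
    nruns: int = 1000,
    seed: int = 0,
    allowed_chroms: tuple[str, ...] = DM6_ARMS,
) -> ProximityTestResult:
    """Monte-Carlo test for genomic clustering of hit genes.

    The observed statistic is the number of hit genes whose nearest
    other hit gene is closer than ``window`` bp (gap between gene
    bodies).  The null redraws the same number of genes uniformly
    without replacement from the annotation restricted to
    ``allowed_chroms``, ``nruns`` times; the p-value is
    (NGE + 1) / (nruns + 1) with NGE the number of null draws reaching
    the observed count.
    """
    ann = annotation[annotation["chrom"].isin(allowed_chroms)].reset_index(drop=True)
    hits = list(hits)
    by_name = ann.set_index("name")
    missing = [h for h in hits if h not in by_name.index]
    if missing:
        raise ValueError(f"hit genes absent from annotation/allowed chroms: {missing[:5]}")
    if len(hits) > len(ann):
        raise ValueError("more hits than annotated genes")

    codes = pd.Categorical(ann["chrom"]).codes.astype(np.int64)
    starts = ann["start"].to_numpy(np.int64)
    ends = ann["end"].to_numpy(np.int64)
    pos = {name: i for i, name in enumerate(ann["name"])}
    hit_idx = np.array([pos[h] for h in hits], dtype=np.int64)

    observed = _count_close_genes(codes[hit_idx], starts[hit_idx], ends[hit_idx], window)

    rng = np.random.default_rng(seed)
    null = np.empty(nruns, dtype=np.int64)
    for r in range(nruns):
        pick = rng.choice(len(ann), size=len(hits), replace=False)
        null[r] = _count_close_genes(codes[pick], starts[pick], ends[pick], window)

    nge = int((null >= observed).sum())
    p = (nge + 1) / (nruns + 1)
    return ProximityTestResult(
        observed_count=int(observed),
        null_counts=null,
        null_median=float(np.median(null)),
        p_value=float(p),
        n_hits=len(hits),
        nruns=nruns,
    )


def call_hits(
    table: pd.DataFrame,
    fdr_threshold: float = 0.05,
    gatc_min: int = 1,
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Filter + PCA-regression hit calling in one step."""
    return pca_regression_hits(
        filter_genes(table, fdr_threshold, gatc_min), z_threshold
    )
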