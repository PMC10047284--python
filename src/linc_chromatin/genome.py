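"""Coarse-grained bead representation of the genome.

The fly genome (176.2 Mbp) is coarse-grained at 5 kbp per bead of diameter
sigma = 30 nm, split into four chromosomes modelled as linear bead-spring
chains.  Each chain carries a contiguous pericentromeric-heterochromatin
(PCH) block (30% of beads by default) with euchromatin (EU) elsewhere.
H3K27me3 domains are laid down as non-overlapping patches with
exponentially distributed lengths (mean 17 beads) until a target genome
coverage (40% by default) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

EU = 0
PCH = 1

_COMPARTMENT_NAMES = {EU: "EU", PCH: "PCH"}


@dataclass
class GenomeSpec:
    """Parameters of the coarse-grained genome.

    Defaults describe the Drosophila melanogaster muscle-nucleus model:
    176.2 Mbp at 5 kbp/bead, four chromosome arms, a 70/30 EU/PCH split,
    and H3K27me3 covering 40% of the genome in exponential patches of
    mean length 17 beads.  ``eu_h3k27me3_coverage`` and
    ``pch_h3k27me3_coverage`` are only used by the per-compartment patch
    mode (22% of EU, 77.5% of PCH).
    """

    genome_length_bp: int = 176_200_000
    bp_per_bead: int = 5000
    bead_diameter_sigma: float = 30.0  # nm
    n_chromosomes: int = 4
    frac_euchromatin: float = 0.70
    frac_pch: float = 0.30
    h3k27me3_target_coverage: float = 0.40
    mean_patch_len_beads: float = 17.0
    eu_h3k27me3_coverage: float = 0.22
    pch_h3k27me3_coverage: float = 0.775
    chromosome_fractions: Sequence[float] | None = None
    pch_placement: Literal["center", "end"] = "center"

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0 or self.bp_per_bead <= 0:
            raise ValueError("genome_length_bp and bp_per_bead must be positive")
        if not np.isclose(self.frac_euchromatin + self.frac_pch, 1.0):
            raise ValueError("frac_euchromatin + frac_pch must equal 1")
        if not 0.0 <= self.h3k27me3_target_coverage < 1.0:
            raise ValueError("h3k27me3_target_coverage must lie in [0, 1)")
        if self.mean_patch_len_beads < 1:
            raise ValueError("mean_patch_len_beads must be >= 1")
        if not 0.0 <= self.frac_pch <= 1.0:
            raise ValueError("frac_pch must lie in [0, 1]")
        if self.chromosome_fractions is not None:
            fr = np.asarray(self.chromosome_fractions, dtype=float)
            if len(fr) != self.n_chromosomes or not np.isclose(fr.sum(), 1.0):
                raise ValueError(
                    "chromosome_fractions must have n_chromosomes entries summing to 1"
                )


@dataclass
class ChromatinBeadSequence:
    """Per-bead compartment labels, H3K27me3 flags and chromosome bounds.

    ``labels`` holds EU (0) / PCH (1) codes; ``h3k27me3`` is a boolean
    flag per bead; ``chromosome_bounds`` are half-open bead-index
    intervals.  ``patches`` records the (start, length) bookkeeping of
    every generated H3K27me3 patch and must reconstruct the flag vector
    exactly.
    """

    labels: np.ndarray
    h3k27me3: np.ndarray
    chromosome_bounds: list[tuple[int, int]]
    patches: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.h3k27me3 = np.asarray(self.h3k27me3, dtype=bool)
        if self.labels.shape != self.h3k27me3.shape:
            raise ValueError("labels and h3k27me3 must have equal length")
        n = len(self.labels)
        covered = np.zeros(n, dtype=bool)
        for start, end in self.chromosome_bounds:
            if not 0 <= start < end <= n:
                raise ValueError(f"invalid chromosome interval ({start}, {end})")
            if covered[start:end].any():
                raise ValueError("chromosome intervals overlap")
            covered[start:end] = True
        if not covered.all():
            raise ValueError("chromosome intervals must cover all beads")

    @property
    def n_beads(self) -> int:
        return len(self.labels)

    def chromosome_of(self, bead: int) -> int:
        for c, (s, e) in enumerate(self.chromosome_bounds):
            if s <= bead < e:
                return c
        raise IndexError(bead)

    def bead_types(self) -> np.ndarray:
        """Interaction types: 0 = EU, 1 = PCH, 2 = H3K27me3-flagged."""
        types = self.labels.astype(np.int8).copy()
        types[self.h3k27me3] = 2
        return types

    def to_dataframe(self) -> pd.DataFrame:
        chrom = np.empty(self.n_beads, dtype=np.int32)
        for c, (s, e) in enumerate(self.chromosome_bounds):
            chrom[s:e] = c
        return pd.DataFrame(
            {
                "bead_index": np.arange(self.n_beads),
                "chromosome": chrom,
                "compartment": [_COMPARTMENT_NAMES[int(x)] for x in self.labels],
                "h3k27me3": self.h3k27me3.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChromatinBeadSequence":
        df = pd.read_csv(path, sep="\t")
        labels = np.array([PCH if c == "PCH" else EU for c in df["compartment"]], dtype=np.uint8)
        flags = df["h3k27me3"].to_numpy(dtype=bool)
        bounds = []
        chroms = df["chromosome"].to_numpy()
        for c in np.unique(chroms):
            idx = np.flatnonzero(chroms == c)
            bounds.append((int(idx[0]), int(idx[-1]) + 1))
        return cls(labels=labels, h3k27me3=flags, chromosome_bounds=bounds)


def compute_bead_count(genome_length_bp: int, bp_per_bead: int) -> int:
    """Number of beads for a genome at a given coarse-graining.

    Rounds half-up, so 176.2 Mbp at 5 kbp/bead gives 35,240 beads.
    """
    if genome_length_bp <= 0 or bp_per_bead <= 0:
        raise ValueError("arguments must be positive")
    n = int(np.floor(genome_length_bp / bp_per_bead + 0.5))
    return max(n, 1)


def partition_genome(spec: GenomeSpec, n_beads: int) -> ChromatinBeadSequence:
    """Split beads into chromosomes and assign EU/PCH compartments.

    Chromosomes are contiguous chains of (by default) equal length, the
    remainder going to the last chain.  Each chain carries one
    contiguous PCH block whose size is its proportional share of
    round(frac_pch * n_beads), placed at the chain midpoint (or chain
    end, per ``spec.pch_placement``).
    """
    if n_beads < spec.n_chromosomes:
        raise ValueError("need at least one bead per chromosome")

    k = spec.n_chromosomes
    if spec.chromosome_fractions is None:
        base = n_beads // k
        sizes = [base] * k
        sizes[-1] += n_beads - base * k
    else:
        fr = np.asarray(spec.chromosome_fractions, dtype=float)
        sizes = _largest_remainder(fr * n_beads, n_beads)

    bounds: list[tuple[int, int]] = []
    start = 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s

    total_pch = int(np.floor(spec.frac_pch * n_beads + 0.5))
    pch_per_chain = _largest_remainder(
        np.asarray(sizes, dtype=float) * (total_pch / n_beads) * (n_beads / sum(sizes)),
        total_pch,
    )

    labels = np.zeros(n_beads, dtype=np.uint8)
    for (s, e), m in zip(bounds, pch_per_chain):
        chain_len = e - s
        m = min(m, chain_len)
        if m == 0:
            continue
        if spec.pch_placement == "center":
            off = (chain_len - m) // 2
        else:
            off = chain_len - m
        labels[s + off : s + off + m] = PCH

    return ChromatinBeadSequence(
        labels=labels,
        h3k27me3=np.zeros(n_beads, dtype=bool),
        chromosome_bounds=bounds,
    )


def _largest_remainder(quotas: np.ndarray, total: int) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``quotas``."""
    quotas = np.asarray(quotas, dtype=float)
    if quotas.sum() == 0:
        out = np.zeros(len(quotas), dtype=int)
        out[-1] = total
        return out.tolist()
    scaled = quotas / quotas.sum() * total
    floors = np.floor(scaled).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(scaled - floors))
    floors[order[:short]] += 1
    return floors.tolist()


def generate_h3k27me3_patches(
    seq: ChromatinBeadSequence,
    spec: GenomeSpec,
    seed: int,
    mode: Literal["global", "per_compartment"] = "global",
) -> ChromatinBeadSequence:
    """Lay down non-overlapping H3K27me3 patches by rejection sampling.

    Patch lengths are drawn from an exponential distribution with mean
    ``spec.mean_patch_len_beads`` (rounded, floored at 1 bead); start
    positions are uniform over beads.  A proposal is rejected if it
    would overlap an existing patch or straddle a chromosome boundary.
    Sampling stops the first time flagged coverage reaches the target,
    so the final fraction overshoots by less than one patch length.

    ``mode="global"`` targets ``h3k27me3_target_coverage`` of the whole
    genome uniformly.  ``mode="per_compartment"`` instead covers
    ``eu_h3k27me3_coverage`` of EU and ``pch_h3k27me3_coverage`` of PCH
    separately (patches then also stay within their compartment).
    """
    if seq.h3k27me3.any():
        raise ValueError("sequence already carries H3K27me3 flags")

    rng = np.random.default_rng(seed)
    flags = np.zeros(seq.n_beads, dtype=bool)
    patches: list[tuple[int, int]] = []

    if mode == "global":
        jobs = [(seq.chromosome_bounds, np.arange(seq.n_beads), spec.h3k27me3_target_coverage)]
    elif mode == "per_compartment":
        jobs = []
        for comp, cov in ((EU, spec.eu_h3k27me3_coverage), (PCH, spec.pch_h3k27me3_coverage)):
            segs = _compartment_segments(seq, comp)
            beads = np.flatnonzero(seq.labels == comp)
            if len(beads):
                jobs.append((segs, beads, cov))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for segments, candidate_beads, target in jobs:
        if target >= 0.95:
            raise ValueError(
                "target coverage >= 0.95 puts rejection sampling in a "
                "non-terminating regime"
            )
        if target <= 0:
            continue
        n_sub = len(candidate_beads)
        seg_starts = np.array([s for s, _ in segments])
        seg_ends = np.array([e for _, e in segments])
        needed = target * n_sub
        flagged = 0
        failures = 0
        # Positions (not lengths) are resampled on rejection, so the
        # accepted patch-length distribution keeps the exponential's mean.
        max_pos_attempts = 200 + 20 * n_sub // max(1, int(spec.mean_patch_len_beads))
        while flagged < needed:
            L = max(1, int(np.floor(rng.exponential(spec.mean_patch_len_beads) + 0.5)))
            placed = False
            for _ in range(max_pos_attempts):
                start = int(candidate_beads[rng.integers(n_sub)])
                iseg = np.searchsorted(seg_starts, start, side="right") - 1
                if iseg < 0 or start >= seg_ends[iseg]:
                    continue
                if start + L > seg_ends[iseg]:
                    continue  # would cross a chromosome/compartment boundary
                if flags[start : start + L].any():
                    continue  # would overlap an existing patch
                flags[start : start + L] = True
                patches.append((start, L))
                flagged += L
                placed = True
                break
            if not placed:
                failures += 1
                if failures > 1000:
                    raise RuntimeError("patch rejection sampling failed to converge")

    patches.sort()
    return ChromatinBeadSequence(
        labels=seq.labels.copy(),
        h3k27me3=flags,
        chromosome_bounds=list(seq.chromosome_bounds),
        patches=patches,
    )


def _compartment_segments(seq: ChromatinBeadSequence, comp: int) -> list[tuple[int, int]]:
    """Maximal runs of one compartment that stay within a chromosome."""
    segs: list[tuple[int, int]] = []
    for s, e in seq.chromosome_bounds:
        lab = seq.labels[s:e]
        if len(lab) == 0:
            continue
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(lab)]])
        for a, b in zip(starts, ends):
            if lab[a] == comp:
                segs.append((s + int(a), s + int(b)))
    return segs


@dataclass
class PatchStatistics:
    n_patches: int
    mean_len: float | None
    coverage: float
    eu_coverage: float
    pch_coverage: float
    patch_lengths: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def patch_statistics(seq: ChromatinBeadSequence) -> PatchStatistics:
    """Summarize maximal flagged runs: count, mean length, coverage."""
    flags = seq.h3k27me3.astype(np.int8)
    n = len(flags)
    if n == 0:
        return PatchStatistics(0, None, 0.0, 0.0, 0.0)
    diff = np.diff(np.concatenate([[0], flags, [0]]))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    lengths = ends - starts
    eu = seq.labels == EU
    pch = seq.labels == PCH
    return PatchStatistics(
        n_patches=len(lengths),
        mean_len=float(lengths.mean()) if len(lengths) else None,
        coverage=float(flags.sum() / n),
        eu_coverage=float(seq.h3k27me3[eu].mean()) if eu.any() else 0.0,
        pch_coverage=float(seq.h3k27me3[pch].mean()) if pch.any() else 0.0,
        patch_lengths=lengths,
    )


def build_genome(spec: GenomeSpec, seed: int, mode: str = "global") -> ChromatinBeadSequence:
    """Convenience: bead count -> partition -> H3K27me3 patches."""
    n = compute_bead_count(spec.genome_length_bp, spec.bp_per_bead)
    seq = partition_genome(spec, n)
    return generate_h3k27me3_patches(seq, spec, seed=seed, mode=mode)
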