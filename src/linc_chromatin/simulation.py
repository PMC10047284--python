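"""Langevin dynamics of bead-spring chromosomes in a spherical nucleus.

Chromosomes are flexible bead-spring chains confined to a sphere whose
radius sets a 15% chromatin volume fraction.  The inner surface is
tiled with fixed lamina beads.  Bead types attract via a truncated
Lennard-Jones potential (heterochromatin eps_HH = 0.5 kBT stronger than
euchromatin eps_EE = 0.35 kBT, cross pairs 0.3 kBT), and H3K27me3 beads
dynamically form/break a harmonic bond of stiffness K with the nearest
lamina bead: formed when closer than 1.5 sigma, broken beyond 2.5
sigma, at most one bond per chromatin bead.

The integrator is overdamped (Brownian) Euler-Maruyama with kBT = 1 and
gamma = 1: the simplest scheme with the correct equilibrium statistics
for a model whose claims are about steady-state organization, not
kinetics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .genome import ChromatinBeadSequence


class SimulationDivergedError(RuntimeError):
    """A coordinate became non-finite during integration."""

    def __init__(self, step: int):
        super().__init__(f"simulation diverged at step {step}")
        self.step = step


@dataclass
class SimulationConfig:
    """Physical and numerical parameters (lengths in sigma, energies in kBT).

    ``timestep`` defaults to 0.002 tau: with backbone stiffness k = 100
    kBT/sigma^2 the stiffest chain mode has effective rate 4k/gamma, and
    explicit Euler requires k*dt*4 < 2 for stability.
    """

    eps_EE: float = 0.35
    eps_HH: float = 0.5
    eps_cross: float = 0.3
    lj_cutoff: float = 2.5
    backbone_k: float = 100.0
    backbone_rest: float = 1.0
    lamina_bond_K: float = 10.0
    bond_form_dist: float = 1.5
    bond_break_dist: float = 2.5
    bond_rest: float = 1.0
    volume_fraction: float = 0.15
    timestep: float = 0.002
    damping: float = 1.0
    temperature: float = 1.0
    lamina_spacing: float = 1.0
    eps_lamina: float = 1.0
    registry_stride: int = 10
    force_cap: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bond_form_dist < self.bond_break_dist:
            raise ValueError("bond_form_dist must be < bond_break_dist")
        if not 0.0 < self.volume_fraction < 0.64:
            raise ValueError("volume_fraction must lie in (0, 0.64)")
        for name in ("eps_EE", "eps_HH", "eps_cross"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.timestep <= 0 or self.damping <= 0:
            raise ValueError("timestep and damping must be positive")

    def eps_table(self) -> np.ndarray:
        """3x3 LJ epsilon by bead type (0 EU, 1 PCH, 2 H3K27me3).

        PCH and H3K27me3 are both heterochromatin and share eps_HH;
        EU-heterochromatin pairs use eps_cross.
        """
        t = np.empty((3, 3))
        t[0, 0] = self.eps_EE
        t[1:, 1:] = self.eps_HH
        t[0, 1:] = t[1:, 0] = self.eps_cross
        return t


@dataclass
class SimulationState:
    """Mobile-bead positions plus everything needed to evolve them."""

    positions: np.ndarray  # (n, 3) sigma
    lamina_positions: np.ndarray  # (m, 3), fixed, |r| = R
    bond_partner: np.ndarray  # (n,) lamina index or -1
    types: np.ndarray  # (n,) 0 EU / 1 PCH / 2 H3K27me3
    chain_bounds: np.ndarray  # (n_chains, 2) half-open bead intervals
    R: float
    step_count: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def bond_registry(self) -> dict[int, int]:
        idx = np.flatnonzero(self.bond_partner >= 0)
        return {int(i): int(self.bond_partner[i]) for i in idx}

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            lamina_positions=self.lamina_positions,
            bond_partner=self.bond_partner.copy(),
            types=self.types,
            chain_bounds=self.chain_bounds,
            R=self.R,
            step_count=self.step_count,
        )


def confinement_radius(n_beads: int, volume_fraction: float = 0.15) -> float:
    """Sphere radius (sigma) at which n beads of diameter 1 fill the
    given volume fraction: R = (n / (8 f))^(1/3)."""
    if n_beads <= 0:
        raise ValueError("n_beads must be positive")
    if not 0.0 < volume_fraction < 0.64:
        raise ValueError("volume_fraction must lie in (0, 0.64)")
    return float((n_beads / (8.0 * volume_fraction)) ** (1.0 / 3.0))


def build_lamina(R: float, spacing: float = 1.0) -> np.ndarray:
    """Near-uniform Fibonacci lattice on the sphere of radius R.

    The point count is chosen so the mean nearest-neighbor distance is
    approximately ``spacing``.
    """
    if R <= 1:
        raise ValueError("R must exceed one bead diameter")
    n = max(1, int(round(4.0 * np.pi * R * R / (spacing * spacing))))
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return R * pts


def pair_energy(r, eps: float, cutoff: float = 2.5):
    """Truncated, energy-shifted Lennard-Jones potential (sigma = 1)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (r -> 0 is the capped-force regime)")
    shift = 4.0 * eps * (cutoff**-12 - cutoff**-6)
    u = np.where(r <= cutoff, 4.0 * eps * (r**-12.0 - r**-6.0) - shift, 0.0)
    return u if u.ndim else float(u)


def update_lamina_bonds(
    state: SimulationState, config: SimulationConfig, lam_tree: cKDTree | None = None
) -> SimulationState:
    """Apply the dynamic-bond rules to the registry (in place).

    First every bond stretched beyond ``bond_break_dist`` is removed;
    then every unbonded H3K27me3 bead within ``bond_form_dist`` of a
    lamina bead bonds to the nearest one.  Lamina beads may host
    multiple bonds; chromatin beads at most one.
    """
    if lam_tree is None:
        lam_tree = cKDTree(state.lamina_positions)
    bonded = np.flatnonzero(state.bond_partner >= 0)
    if len(bonded):
        d = np.linalg.norm(
            state.positions[bonded]
            - state.lamina_positions[state.bond_partner[bonded]],
            axis=1,
        )
        state.bond_partner[bonded[d > config.bond_break_dist]] = -1
    free = np.flatnonzero((state.types == 2) & (state.bond_partner < 0))
    if len(free):
        dist, idx = lam_tree.query(state.positions[free], k=1)
        hit = dist < config.bond_form_dist
        state.bond_partner[free[hit]] = idx[hit]
    return state


def _grid_params(R: float, cutoff: float) -> tuple[float, float, int]:
    # half-cutoff cells: the kernel scans +/-2 cells, which tightens the
    # scanned volume versus cutoff-sized cells; the grid is capped at
    # 128^3 cells for very large R (cells may only grow, which keeps the
    # +/-2 scan correct)
    cell = cutoff / 2.0
    M = int(np.ceil((2.0 * (R + 2.0 * cell)) / cell)) + 1
    if M > 128:
        cell = 2.0 * R / 124.0
        M = int(np.ceil((2.0 * (R + 2.0 * cell)) / cell)) + 1
    origin = -(R + 2.0 * cell)
    return origin, cell, M


def _advance(
    state: SimulationState,
    config: SimulationConfig,
    n_steps: int,
    rng: np.random.Generator,
    *,
    lam_cells=None,
    dt: float | None = None,
    temperature: float | None = None,
    force_cap: float | None = None,
) -> None:
    """Integrate ``n_steps`` without touching the bond registry."""
    if n_steps <= 0:
        return
    dt = config.timestep if dt is None else dt
    kT = config.temperature if temperature is None else temperature
    fcap = config.force_cap if force_cap is None else force_cap
    origin, cell, M = _grid_params(state.R, config.lj_cutoff)
    if lam_cells is None:
        lam_head, lam_next = _kernels.build_cell_list(
            np.ascontiguousarray(state.lamina_positions), origin, cell, M
        )
    else:
        lam_head, lam_next = lam_cells
    amp = np.sqrt(2.0 * kT * dt / config.damping)
    if amp > 0:
        noise = rng.standard_normal((n_steps, state.n_beads, 3)) * amp
    else:
        noise = np.zeros((n_steps, state.n_beads, 3))
    bad = _kernels.advance_chunk(
        state.positions,
        state.types.astype(np.int64),
        state.chain_bounds[:, 0].astype(np.int64),
        state.chain_bounds[:, 1].astype(np.int64),
        state.bond_partner,
        np.ascontiguousarray(state.lamina_positions),
        lam_head,
        lam_next,
        origin,
        cell,
        M,
        noise,
        dt,
        1.0 / config.damping,
        config.eps_table(),
        config.lj_cutoff,
        config.backbone_k,
        config.backbone_rest,
        config.lamina_bond_K,
        config.bond_rest,
        config.eps_lamina,
        fcap,
        state.R,
    )
    if bad >= 0:
        raise SimulationDivergedError(state.step_count + bad)
    state.step_count += n_steps


def step(
    state: SimulationState,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """One overdamped Langevin step (returns the same state, mutated).

    The bond registry is refreshed every ``config.registry_stride``
    steps, counted from ``state.step_count``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _advance(state, config, 1, rng)
    if state.step_count % config.registry_stride == 0:
        update_lamina_bonds(state, config)
    return state


@dataclass
class Trajectory:
    """Frames of a simulation run (positions + bond registry per frame)."""

    frames_positions: np.ndarray  # (F, n, 3) float32
    frames_bonds: np.ndarray  # (F, n) int32
    frame_steps: np.ndarray  # (F,)
    types: np.ndarray
    chain_bounds: np.ndarray
    lamina_positions: np.ndarray
    R: float
    config: SimulationConfig
    stride: int = 1

    @property
    def n_frames(self) -> int:
        return self.frames_positions.shape[0]

    def frame(self, i: int) -> SimulationState:
        return SimulationState(
            positions=self.frames_positions[i].astype(np.float64),
            lamina_positions=self.lamina_positions,
            bond_partner=self.frames_bonds[i].astype(np.int64),
            types=self.types,
            chain_bounds=self.chain_bounds,
            R=self.R,
            step_count=int(self.frame_steps[i]),
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            frames_positions=self.frames_positions,
            frames_bonds=self.frames_bonds,
            frame_steps=self.frame_steps,
            types=self.types,
            chain_bounds=self.chain_bounds,
            lamina_positions=self.lamina_positions,
            R=np.array(self.R),
            stride=np.array(self.stride),
            config_json=np.array(json.dumps(asdict(self.config))),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as z:
            config = SimulationConfig(**json.loads(str(z["config_json"])))
            return cls(
                frames_positions=z["frames_positions"],
                frames_bonds=z["frames_bonds"],
                frame_steps=z["frame_steps"],
                types=z["types"],
                chain_bounds=z["chain_bounds"],
                lamina_positions=z["lamina_positions"],
                R=float(z["R"]),
                config=config,
                stride=int(z["stride"]),
            )

    def export_xyz(self, path) -> None:
        """XYZ trajectory with element tags E/P/H for chromatin, L for lamina."""
        tags = np.array(["E", "P", "H"])[self.types]
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                n_total = len(tags) + len(self.lamina_positions)
                fh.write(f"{n_total}\nstep {int(self.frame_steps[f])}\n")
                for tag, p in zip(tags, self.frames_positions[f]):
                    fh.write(f"{tag} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
                for p in self.lamina_positions:
                    fh.write(f"L {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def initialize_state(
    seq: ChromatinBeadSequence,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulationState:
    """Confined random-walk chains, then a short athermal relaxation to
    push overlapping beads apart."""
    n = seq.n_beads
    R = confinement_radius(n, config.volume_fraction)
    lamina = build_lamina(R, config.lamina_spacing)
    chain_bounds = np.array(seq.chromosome_bounds, dtype=np.int64)

    pos = np.empty((n, 3))
    rmax = max(R - 1.0, 0.5 * R)
    for s, e in seq.chromosome_bounds:
        # random starting point well inside the sphere
        while True:
            p = rng.uniform(-0.7 * R, 0.7 * R, 3)
            if np.linalg.norm(p) < 0.7 * R:
                break
        pos[s] = p
        for b in range(s + 1, e):
            stepv = rng.standard_normal(3)
            stepv /= np.linalg.norm(stepv)
            q = pos[b - 1] + stepv
            ri = np.linalg.norm(q)
            if ri > rmax:
                q *= max((2.0 * rmax - ri), 0.3 * rmax) / ri
            pos[b] = q

    state = SimulationState(
        positions=pos,
        lamina_positions=lamina,
        bond_partner=np.full(n, -1, dtype=np.int64),
        types=seq.bead_types().astype(np.int64),
        chain_bounds=chain_bounds,
        R=R,
    )
    # athermal relaxation with a small step and tight force cap
    _advance(state, config, 500, rng, dt=5e-4, temperature=0.0, force_cap=50.0)
    state.step_count = 0
    return state


def run_simulation(
    seq: ChromatinBeadSequence,
    config: SimulationConfig,
    steps: int,
    stride: int = 100,
    seed: int | None = None,
) -> Trajectory:
    """Full pipeline: initialize, integrate, sample frames every ``stride``.

    Returns floor(steps/stride) + 1 frames (the first is the relaxed
    initial configuration).  Fully reproducible given the seed.
    """
    if stride < 1 or (steps > 0 and steps < stride):
        raise ValueError("need steps >= stride >= 1")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    state = initialize_state(seq, config, rng)
    lam_tree = cKDTree(state.lamina_positions)
    update_lamina_bonds(state, config, lam_tree)

    origin, cell, M = _grid_params(state.R, config.lj_cutoff)
    lam_cells = _kernels.build_cell_list(
        np.ascontiguousarray(state.lamina_positions), origin, cell, M
    )

    n_frames = steps // stride + 1
    fpos = np.empty((n_frames, state.n_beads, 3), dtype=np.float32)
    fbond = np.empty((n_frames, state.n_beads), dtype=np.int32)
    fstep = np.empty(n_frames, dtype=np.int64)

    def record(k: int) -> None:
        fpos[k] = state.positions
        fbond[k] = state.bond_partner
        fstep[k] = state.step_count

    record(0)
    k = 1
    done = 0
    next_frame = stride
    next_bond = config.registry_stride
    while done < steps:
        upto = min(steps, next_frame, next_bond)
        _advance(state, config, upto - done, rng, lam_cells=lam_cells)
        done = upto
        if done == next_bond:
            update_lamina_bonds(state, config, lam_tree)
            next_bond += config.registry_stride
        if done == next_frame:
            record(k)
            k += 1
            next_frame += stride
    return Trajectory(
        frames_positions=fpos,
        frames_bonds=fbond,
        frame_steps=fstep,
        types=state.types,
        chain_bounds=state.chain_bounds,
        lamina_positions=state.lamina_positions,
        R=state.R,
        config=replace(config, seed=seed),
        stride=stride,
    )
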