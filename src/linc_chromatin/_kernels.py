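"""Numba kernels for the Langevin polymer engine.

Cell-list neighbor search (half-cutoff cells, +/-2-cell scan) keeps the
per-step cost O(N) at fixed density.  All lengths are in bead diameters
(sigma), energies in kBT.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# squared WCA cutoff (2^(1/6))^2 = 2^(1/3)
_WCA_CUT2 = 2.0 ** (1.0 / 3.0)


@njit(cache=True)
def build_cell_list(pos, origin, cell, M):
    """Linked-list cell decomposition of a point set."""
    n = pos.shape[0]
    head = np.full(M * M * M, -1, np.int64)
    nxt = np.empty(n, np.int64)
    for i in range(n):
        ix = int((pos[i, 0] - origin) / cell)
        iy = int((pos[i, 1] - origin) / cell)
        iz = int((pos[i, 2] - origin) / cell)
        c = (ix * M + iy) * M + iz
        nxt[i] = head[c]
        head[c] = i
    return head, nxt


@njit(cache=True, fastmath=True)
def advance_chunk(
    pos,
    types,
    chain_starts,
    chain_ends,
    bond_partner,
    lam_pos,
    lam_head,
    lam_next,
    origin,
    cell,
    M,
    noise,
    dt,
    inv_gamma,
    eps_table,
    cutoff,
    k_bb,
    r0_bb,
    K_bond,
    bond_rest,
    eps_lam,
    fcap,
    R,
):
    """Advance ``noise.shape[0]`` overdamped Langevin steps in place.

    ``noise`` must already be scaled to sqrt(2 kBT dt / gamma) per
    coordinate.  Returns -1 on success or the index of the sub-step at
    which a non-finite coordinate appeared.
    """
    n = pos.shape[0]
    nsub = noise.shape[0]
    ncell = M * M * M
    cutoff2 = cutoff * cutoff
    head = np.full(ncell, -1, np.int64)
    nxt = np.empty(n, np.int64)
    bead_cell = np.empty(n, np.int64)  # occupied cell per bead, for sparse clearing
    F = np.empty((n, 3), np.float64)

    for t in range(nsub):
        # --- rebuild mobile cell list, zero forces
        for i in range(n):
            ix = int((pos[i, 0] - origin) / cell)
            iy = int((pos[i, 1] - origin) / cell)
            iz = int((pos[i, 2] - origin) / cell)
            c = (ix * M + iy) * M + iz
            bead_cell[i] = c
            nxt[i] = head[c]
            head[c] = i
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0

        # --- backbone springs
        if k_bb > 0.0:
            for ci in range(chain_starts.shape[0]):
                for b in range(chain_starts[ci], chain_ends[ci] - 1):
                    dx = pos[b + 1, 0] - pos[b, 0]
                    dy = pos[b + 1, 1] - pos[b, 1]
                    dz = pos[b + 1, 2] - pos[b, 2]
                    r = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if r > 1e-12:
                        f = k_bb * (r - r0_bb) / r
                        F[b, 0] += f * dx
                        F[b, 1] += f * dy
                        F[b, 2] += f * dz
                        F[b + 1, 0] -= f * dx
                        F[b + 1, 1] -= f * dy
                        F[b + 1, 2] -= f * dz

        # --- pairwise truncated LJ between mobile beads
        # cell size is cutoff/2, so the scan spans +/-2 cells
        for i in range(n):
            ix = int((pos[i, 0] - origin) / cell)
            iy = int((pos[i, 1] - origin) / cell)
            iz = int((pos[i, 2] - origin) / cell)
            ti = types[i]
            for ax in range(max(0, ix - 2), min(M, ix + 3)):
                for ay in range(max(0, iy - 2), min(M, iy + 3)):
                    for az in range(max(0, iz - 2), min(M, iz + 3)):
                        j = head[(ax * M + ay) * M + az]
                        while j != -1:
                            if j > i:
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                d2 = dx * dx + dy * dy + dz * dz
                                if d2 < cutoff2 and d2 > 1e-16:
                                    eps = eps_table[ti, types[j]]
                                    if eps > 0.0:
                                        inv2 = 1.0 / d2
                                        inv6 = inv2 * inv2 * inv2
                                        # F = 24 eps (2 r^-12 - r^-6) / r^2 * dr
                                        coef = 24.0 * eps * inv2 * (2.0 * inv6 * inv6 - inv6)
                                        fmag = abs(coef) * np.sqrt(d2)
                                        if fmag > fcap:
                                            coef = coef / fmag * fcap
                                        F[i, 0] += coef * dx
                                        F[i, 1] += coef * dy
                                        F[i, 2] += coef * dz
                                        F[j, 0] -= coef * dx
                                        F[j, 1] -= coef * dy
                                        F[j, 2] -= coef * dz
                            j = nxt[j]

        # --- purely repulsive (WCA) contact with fixed lamina beads
        if eps_lam > 0.0 and lam_pos.shape[0] > 0:
            shell = R - cutoff
            shell2 = shell * shell if shell > 0.0 else -1.0
            for i in range(n):
                rc2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
                if rc2 > shell2:
                    ix = int((pos[i, 0] - origin) / cell)
                    iy = int((pos[i, 1] - origin) / cell)
                    iz = int((pos[i, 2] - origin) / cell)
                    for ax in range(max(0, ix - 1), min(M, ix + 2)):
                        for ay in range(max(0, iy - 1), min(M, iy + 2)):
                            for az in range(max(0, iz - 1), min(M, iz + 2)):
                                j = lam_head[(ax * M + ay) * M + az]
                                while j != -1:
                                    dx = pos[i, 0] - lam_pos[j, 0]
                                    dy = pos[i, 1] - lam_pos[j, 1]
                                    dz = pos[i, 2] - lam_pos[j, 2]
                                    d2 = dx * dx + dy * dy + dz * dz
                                    if d2 < _WCA_CUT2 and d2 > 1e-16:
                                        inv2 = 1.0 / d2
                                        inv6 = inv2 * inv2 * inv2
                                        coef = 24.0 * eps_lam * inv2 * (
                                            2.0 * inv6 * inv6 - inv6
                                        )
                                        fmag = abs(coef) * np.sqrt(d2)
                                        if fmag > fcap:
                                            coef = coef / fmag * fcap
                                        F[i, 0] += coef * dx
                                        F[i, 1] += coef * dy
                                        F[i, 2] += coef * dz
                                    j = lam_next[j]

        # --- harmonic H3K27me3-lamina bonds
        if K_bond > 0.0:
            for i in range(n):
                p = bond_partner[i]
                if p >= 0:
                    dx = lam_pos[p, 0] - pos[i, 0]
                    dy = lam_pos[p, 1] - pos[i, 1]
                    dz = lam_pos[p, 2] - pos[i, 2]
                    r = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if r > 1e-12:
                        f = K_bond * (r - bond_rest) / r
                        F[i, 0] += f * dx
                        F[i, 1] += f * dy
                        F[i, 2] += f * dz

        # --- clear only the occupied cells before the next rebuild
        for i in range(n):
            head[bead_cell[i]] = -1

        # --- Euler-Maruyama update + hard reflecting wall at |r| = R
        for i in range(n):
            pos[i, 0] += F[i, 0] * dt * inv_gamma + noise[t, i, 0]
            pos[i, 1] += F[i, 1] * dt * inv_gamma + noise[t, i, 1]
            pos[i, 2] += F[i, 2] * dt * inv_gamma + noise[t, i, 2]
            ri2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
            if not np.isfinite(ri2):
                return t
            if ri2 > R * R:
                ri = np.sqrt(ri2)
                s = (2.0 * R - ri) / ri
                if s <= 0.0:
                    s = 0.5 * R / ri
                pos[i, 0] *= s
                pos[i, 1] *= s
                pos[i, 2] *= s
    return -1
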