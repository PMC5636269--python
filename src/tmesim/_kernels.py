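"""Numba kernels for the hot loops of the lattice engine and the ADE solver.

All stochastic decisions consume pre-drawn uniforms supplied by the caller,
so the kernels themselves are deterministic; agent processing order within a
sub-phase is a caller-supplied permutation.  State codes follow the frozen
table in :mod:`tmesim.config` (1/2/3 cancer PDL1-/PDL1+/dead, 4/5/6 T
effector/cytotoxic/suppressed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighbourhood offsets (26), fixed order.
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if not (dx == 0 and dy == 0 and dz == 0)
    ],
    dtype=np.int64,
)

# Candidate anchor offsets for a daughter 2x2x2 cancer block: touching but
# not overlapping the parent block (Chebyshev distance exactly 2 in anchors).
_CANCER_DIV_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        for dz in range(-2, 3)
        if max(abs(dx), abs(dy), abs(dz)) == 2
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _saulyev_sweep(u, a, reverse):
    """One Saul'yev sweep in flux form.  Each interior face flux is shared
    by its two cells (behind face implicit, ahead face explicit), so the
    sweep conserves total mass exactly; zero-flux faces simply drop the
    face's flux, removing both its explicit term and its implicit part.

    The descending sweep is the exact mirror of the ascending one (the
    stencil is symmetric under reversing all three axes).
    """
    if reverse:
        return _saulyev_sweep_desc(u, a)
    return _saulyev_sweep_asc(u, a)


@njit(cache=True)
def _saulyev_sweep_asc(u, a):
    n0, n1, n2 = u.shape
    out = np.empty_like(u)
    diag = 1.0 - 3.0 * a
    for i in range(n0):
        bi = i > 0          # behind neighbour along axis 0 exists
        ai = i < n0 - 1     # ahead neighbour along axis 0 exists
        for j in range(n1):
            bj = j > 0
            aj = j < n1 - 1
            # k = 0 cell (behind-k ghost: zero-flux adds a*u back)
            coeff0 = 1.0 + 3.0 * a
            rhs = u[i, j, 0] * diag + a * u[i, j, 0]
            rhs += a * out[i - 1, j, 0] if bi else a * u[i, j, 0]
            rhs += a * out[i, j - 1, 0] if bj else a * u[i, j, 0]
            if ai:
                rhs += a * u[i + 1, j, 0]
            else:
                coeff0 -= a
            if aj:
                rhs += a * u[i, j + 1, 0]
            else:
                coeff0 -= a
            if n2 > 1:
                rhs += a * u[i, j, 1]
            else:
                coeff0 -= a
            out[i, j, 0] = rhs / coeff0
            # interior k: only i/j boundary flags remain
            coeff = 1.0 + 3.0 * a
            if not ai:
                coeff -= a
            if not aj:
                coeff -= a
            inv = 1.0 / coeff
            if bi and bj and ai and aj:
                for k in range(1, n2 - 1):
                    out[i, j, k] = (
                        u[i, j, k] * diag
                        + a * (out[i - 1, j, k] + out[i, j - 1, k] + out[i, j, k - 1]
                               + u[i + 1, j, k] + u[i, j + 1, k] + u[i, j, k + 1])
                    ) * inv
            else:
                for k in range(1, n2 - 1):
                    rhs = u[i, j, k] * diag + a * out[i, j, k - 1] + a * u[i, j, k + 1]
                    rhs += a * out[i - 1, j, k] if bi else a * u[i, j, k]
                    rhs += a * out[i, j - 1, k] if bj else a * u[i, j, k]
                    if ai:
                        rhs += a * u[i + 1, j, k]
                    if aj:
                        rhs += a * u[i, j + 1, k]
                    out[i, j, k] = rhs * inv
            # k = n2 - 1 cell (ahead-k ghost: flux dropped from the diagonal)
            if n2 > 1:
                k = n2 - 1
                coeffn = coeff - a
                rhs = u[i, j, k] * diag + a * out[i, j, k - 1]
                rhs += a * out[i - 1, j, k] if bi else a * u[i, j, k]
                rhs += a * out[i, j - 1, k] if bj else a * u[i, j, k]
                if ai:
                    rhs += a * u[i + 1, j, k]
                if aj:
                    rhs += a * u[i, j + 1, k]
                out[i, j, k] = rhs / coeffn
    return out


@njit(cache=True)
def _saulyev_sweep_desc(u, a):
    n0, n1, n2 = u.shape
    out = np.empty_like(u)
    diag = 1.0 - 3.0 * a
    for i in range(n0 - 1, -1, -1):
        bi = i < n0 - 1     # behind neighbour along axis 0 (descending)
        ai = i > 0          # ahead neighbour along axis 0
        for j in range(n1 - 1, -1, -1):
            bj = j < n1 - 1
            aj = j > 0
            # k = n2 - 1 cell (behind-k ghost)
            coeff0 = 1.0 + 3.0 * a
            k = n2 - 1
            rhs = u[i, j, k] * diag + a * u[i, j, k]
            rhs += a * out[i + 1, j, k] if bi else a * u[i, j, k]
            rhs += a * out[i, j + 1, k] if bj else a * u[i, j, k]
            if ai:
                rhs += a * u[i - 1, j, k]
            else:
                coeff0 -= a
            if aj:
                rhs += a * u[i, j - 1, k]
            else:
                coeff0 -= a
            if n2 > 1:
                rhs += a * u[i, j, k - 1]
            else:
                coeff0 -= a
            out[i, j, k] = rhs / coeff0
            # interior k
            coeff = 1.0 + 3.0 * a
            if not ai:
                coeff -= a
            if not aj:
                coeff -= a
            inv = 1.0 / coeff
            if bi and bj and ai and aj:
                for k in range(n2 - 2, 0, -1):
                    out[i, j, k] = (
                        u[i, j, k] * diag
                        + a * (out[i + 1, j, k] + out[i, j + 1, k] + out[i, j, k + 1]
                               + u[i - 1, j, k] + u[i, j - 1, k] + u[i, j, k - 1])
                    ) * inv
            else:
                for k in range(n2 - 2, 0, -1):
                    rhs = u[i, j, k] * diag + a * out[i, j, k + 1] + a * u[i, j, k - 1]
                    rhs += a * out[i + 1, j, k] if bi else a * u[i, j, k]
                    rhs += a * out[i, j + 1, k] if bj else a * u[i, j, k]
                    if ai:
                        rhs += a * u[i - 1, j, k]
                    if aj:
                        rhs += a * u[i, j - 1, k]
                    out[i, j, k] = rhs * inv
            # k = 0 cell (ahead-k ghost)
            if n2 > 1:
                coeffn = coeff - a
                rhs = u[i, j, 0] * diag + a * out[i, j, 1]
                rhs += a * out[i + 1, j, 0] if bi else a * u[i, j, 0]
                rhs += a * out[i, j + 1, 0] if bj else a * u[i, j, 0]
                if ai:
                    rhs += a * u[i - 1, j, 0]
                if aj:
                    rhs += a * u[i, j - 1, 0]
                out[i, j, 0] = rhs / coeffn
    return out


@njit(cache=True)
def ade_substeps(u, a, decay_factor, nsub):
    """Averaged two-sweep alternating-direction-explicit update, ``nsub``
    substeps in place; decay applied as an exact per-substep factor."""
    for _ in range(nsub):
        asc = _saulyev_sweep(u, a, False)
        desc = _saulyev_sweep(u, a, True)
        n0, n1, n2 = u.shape
        for i in range(n0):
            for j in range(n1):
                for k in range(n2):
                    u[i, j, k] = 0.5 * (asc[i, j, k] + desc[i, j, k]) * decay_factor
    return u


@njit(cache=True)
def contact_phase(
    order,
    state,
    ax,
    ay,
    az,
    death_time,
    occ,
    u,
    p_kill_neg,
    p_kill_pos,
    p_ind,
    p_supp,
    induction_on_contact,
    t_now,
    counters,
):
    """T-cell contact actions in caller-shuffled order.

    For each T cell adjacent (Moore) to at least one living cancer agent:
    effector -> cytotoxic deterministically; a cytotoxic cell draws one kill
    attempt against one uniformly chosen adjacent living cancer agent, with
    PDL1 induction on a failed attempt against a PDL1- target (or on mere
    contact when ``induction_on_contact``); independently it is suppressed
    with probability ``p_supp`` when adjacent to a living PDL1+ cancer cell.
    ``counters``: activations, attempts, kills, inductions, suppressions.
    """
    n = occ.shape[0]
    found = np.empty(26, np.int64)
    for oi in range(order.shape[0]):
        i = order[oi]
        s = state[i]
        if s < 4:
            continue
        x = ax[i]
        y = ay[i]
        z = az[i]
        nf = 0
        pos_adj = False
        for m in range(26):
            xx = x + _OFFSETS[m, 0]
            yy = y + _OFFSETS[m, 1]
            zz = z + _OFFSETS[m, 2]
            if xx < 0 or yy < 0 or zz < 0 or xx >= n or yy >= n or zz >= n:
                continue
            j = occ[xx, yy, zz]
            if j < 0 or j == i:
                continue
            sj = state[j]
            if sj == 1 or sj == 2:
                dup = False
                for q in range(nf):
                    if found[q] == j:
                        dup = True
                        break
                if not dup:
                    found[nf] = j
                    nf += 1
                if sj == 2:
                    pos_adj = True
        if nf == 0:
            continue
        if s == 4:  # effector activates on first cancer contact
            state[i] = 5
            s = 5
            counters[0] += 1
        if s == 5:
            t = found[min(int(u[oi, 0] * nf), nf - 1)]
            pk = p_kill_neg if state[t] == 1 else p_kill_pos
            counters[1] += 1
            if u[oi, 1] < pk:
                state[t] = 3
                death_time[t] = t_now
                counters[2] += 1
            elif state[t] == 1 and u[oi, 2] < p_ind:
                state[t] = 2
                pos_adj = True
                counters[3] += 1
            if pos_adj and u[oi, 3] < p_supp:
                state[i] = 6
                counters[4] += 1
        elif s == 6 and induction_on_contact:
            # contact-conditioned induction does not require a kill attempt,
            # so even a suppressed T cell in contact can induce PDL1.
            t = found[min(int(u[oi, 0] * nf), nf - 1)]
            if state[t] == 1 and u[oi, 2] < p_ind:
                state[t] = 2
                counters[3] += 1
    return counters


@njit(cache=True)
def division_phase(
    cand,
    state,
    ax,
    ay,
    az,
    cooldown,
    age,
    divisions,
    death_time,
    alive,
    occ,
    u,
    cancer_cycle,
    t_cycle,
    retry_h,
    n_agents,
    counters,
):
    """Division of eligible agents (caller-filtered and shuffled): daughter
    placed in a uniformly chosen free adjacent site (single voxel for T
    cells, non-overlapping touching 2x2x2 block for cancer); cooldown reset
    for parent and daughter.  Returns the number of daughters appended to the
    agent arrays starting at ``n_agents``.  ``counters``: cancer divisions,
    T-cell divisions, blocked (contact-inhibited) attempts."""
    n = occ.shape[0]
    n_new = 0
    cand_x = np.empty(98, np.int64)
    cand_y = np.empty(98, np.int64)
    cand_z = np.empty(98, np.int64)
    for ci in range(cand.shape[0]):
        i = cand[ci]
        s = state[i]
        is_cancer = s <= 3
        nfree = 0
        if is_cancer:
            for m in range(_CANCER_DIV_OFFSETS.shape[0]):
                nx = ax[i] + _CANCER_DIV_OFFSETS[m, 0]
                ny = ay[i] + _CANCER_DIV_OFFSETS[m, 1]
                nz = az[i] + _CANCER_DIV_OFFSETS[m, 2]
                if nx < 0 or ny < 0 or nz < 0 or nx > n - 2 or ny > n - 2 or nz > n - 2:
                    continue
                free = True
                for bx in range(2):
                    for by in range(2):
                        for bz in range(2):
                            if occ[nx + bx, ny + by, nz + bz] >= 0:
                                free = False
                if free:
                    cand_x[nfree] = nx
                    cand_y[nfree] = ny
                    cand_z[nfree] = nz
                    nfree += 1
        else:
            for m in range(26):
                nx = ax[i] + _OFFSETS[m, 0]
                ny = ay[i] + _OFFSETS[m, 1]
                nz = az[i] + _OFFSETS[m, 2]
                if nx < 0 or ny < 0 or nz < 0 or nx >= n or ny >= n or nz >= n:
                    continue
                if occ[nx, ny, nz] < 0:
                    cand_x[nfree] = nx
                    cand_y[nfree] = ny
                    cand_z[nfree] = nz
                    nfree += 1
        if nfree == 0:
            cooldown[i] = retry_h  # contact inhibition: re-attempt after a delay
            counters[2] += 1
            continue
        k = min(int(u[ci] * nfree), nfree - 1)
        nid = n_agents + n_new
        nx = cand_x[k]
        ny = cand_y[k]
        nz = cand_z[k]
        state[nid] = s
        ax[nid] = nx
        ay[nid] = ny
        az[nid] = nz
        age[nid] = 0.0
        death_time[nid] = np.inf
        alive[nid] = True
        divisions[i] += 1
        divisions[nid] = divisions[i]
        if is_cancer:
            cooldown[i] = cancer_cycle
            cooldown[nid] = cancer_cycle
            for bx in range(2):
                for by in range(2):
                    for bz in range(2):
                        occ[nx + bx, ny + by, nz + bz] = nid
            counters[0] += 1
        else:
            cooldown[i] = t_cycle
            cooldown[nid] = t_cycle
            occ[nx, ny, nz] = nid
            counters[1] += 1
        n_new += 1
    return n_new


@njit(cache=True)
def migration_phase(order, state, ax, ay, az, occ, nmoves, dirs, counters):
    """Random-walk moves in caller-shuffled order.  Each agent attempts
    ``nmoves`` moves to uniformly chosen Moore-adjacent sites; a move whose
    target block is not entirely free (or leaves the lattice) is forfeited.
    ``counters``: successful moves, forfeited moves."""
    n = occ.shape[0]
    for oi in range(order.shape[0]):
        i = order[oi]
        sz = 2 if state[i] <= 3 else 1
        for m in range(nmoves[oi]):
            d = dirs[oi, m]
            nx = ax[i] + _OFFSETS[d, 0]
            ny = ay[i] + _OFFSETS[d, 1]
            nz = az[i] + _OFFSETS[d, 2]
            if nx < 0 or ny < 0 or nz < 0 or nx > n - sz or ny > n - sz or nz > n - sz:
                counters[1] += 1
                continue
            free = True
            for bx in range(sz):
                for by in range(sz):
                    for bz in range(sz):
                        o = occ[nx + bx, ny + by, nz + bz]
                        if o >= 0 and o != i:
                            free = False
            if not free:
                counters[1] += 1
                continue
            for bx in range(sz):
                for by in range(sz):
                    for bz in range(sz):
                        occ[ax[i] + bx, ay[i] + by, az[i] + bz] = -1
            for bx in range(sz):
                for by in range(sz):
                    for bz in range(sz):
                        occ[nx + bx, ny + by, nz + bz] = i
            ax[i] = nx
            ay[i] = ny
            az[i] = nz
            counters[0] += 1
    return counters
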