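"""Numba-compiled inner loop of the lattice Monte Carlo simulation.

The kernel mutates the chain state in place and is free of Python objects:
positions are an (n_monomers, 3) int64 array of unwrapped coordinates, the
occupancy is a dense (box, box, box) uint8 array of wrapped sites (all eight
cube corners per monomer in the BFM, one site per monomer otherwise), and
bond validity / inverse bond lengths are looked up in small tables indexed
by component offsets in [-4, 4].

Randomness comes from numba's thread-local NumPy-compatible generator; call
:func:`seed_rng` once per run for reproducible streams.
"""

import math

import numpy as np
from numba import njit

#: lookup-table component offset: bond components stay within [-4, 4]
OFF = 4


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def mc_sweep(pos, occ, mask, moves, allowed, inv_len, cube_mode,
             form_flag, k, energy, n_attempts):
    """Attempt ``n_attempts`` single-monomer moves; Metropolis on bending energy.

    Returns (energy, accepted_count).  ``cube_mode`` selects 2x2x2-cube
    excluded volume (BFM) versus single-site monomers; ``form_flag`` is 0 for
    the cosine-angle potential k(1-c) and 1 for the squared form k(1-c)^2.
    ``mask`` is box_length - 1; the box edge must be a power of two so that
    wrapping reduces to a bitwise AND.
    """
    n_mon = pos.shape[0]
    nb = n_mon - 1
    n_moves = moves.shape[0]
    acc = 0
    for _ in range(n_attempts):
        r = np.random.randint(0, n_mon * n_moves)
        i = r // n_moves
        m = r - i * n_moves
        dx = moves[m, 0]
        dy = moves[m, 1]
        dz = moves[m, 2]
        nxp = pos[i, 0] + dx
        nyp = pos[i, 1] + dy
        nzp = pos[i, 2] + dz

        # bond-length constraint with both neighbours
        if i > 0:
            bx = nxp - pos[i - 1, 0] + OFF
            by = nyp - pos[i - 1, 1] + OFF
            bz = nzp - pos[i - 1, 2] + OFF
            if not allowed[bx, by, bz]:
                continue
        if i < nb:
            bx = pos[i + 1, 0] - nxp + OFF
            by = pos[i + 1, 1] - nyp + OFF
            bz = pos[i + 1, 2] - nzp + OFF
            if not allowed[bx, by, bz]:
                continue

        # excluded volume at the destination
        ox = pos[i, 0]
        oy = pos[i, 1]
        oz = pos[i, 2]
        blocked = False
        if cube_mode:
            for a in range(2):
                sx = nxp + a
                ins_x = 0 <= sx - ox <= 1
                for b in range(2):
                    sy = nyp + b
                    ins_y = 0 <= sy - oy <= 1
                    for c in range(2):
                        sz = nzp + c
                        # sites inside the monomer's own old cube are its own
                        if ins_x and ins_y and 0 <= sz - oz <= 1:
                            continue
                        if occ[sx & mask, sy & mask, sz & mask]:
                            blocked = True
                            break
                    if blocked:
                        break
                if blocked:
                    break
        else:
            if occ[nxp & mask, nyp & mask, nzp & mask]:
                blocked = True
        if blocked:
            continue

        # bending-energy change over the (at most three) affected angles
        dE = 0.0
        for t in range(3):
            a0 = i - 2 + t
            if a0 < 0 or a0 > nb - 2:
                continue
            # old angle a0: bonds (a0 -> a0+1), (a0+1 -> a0+2)
            b1x = pos[a0 + 1, 0] - pos[a0, 0]
            b1y = pos[a0 + 1, 1] - pos[a0, 1]
            b1z = pos[a0 + 1, 2] - pos[a0, 2]
            b2x = pos[a0 + 2, 0] - pos[a0 + 1, 0]
            b2y = pos[a0 + 2, 1] - pos[a0 + 1, 1]
            b2z = pos[a0 + 2, 2] - pos[a0 + 1, 2]
            c_old = (b1x * b2x + b1y * b2y + b1z * b2z) * \
                inv_len[b1x + OFF, b1y + OFF, b1z + OFF] * \
                inv_len[b2x + OFF, b2y + OFF, b2z + OFF]
            # new angle with monomer i displaced
            p0x = nxp if a0 == i else pos[a0, 0]
            p0y = nyp if a0 == i else pos[a0, 1]
            p0z = nzp if a0 == i else pos[a0, 2]
            p1x = nxp if a0 + 1 == i else pos[a0 + 1, 0]
            p1y = nyp if a0 + 1 == i else pos[a0 + 1, 1]
            p1z = nzp if a0 + 1 == i else pos[a0 + 1, 2]
            p2x = nxp if a0 + 2 == i else pos[a0 + 2, 0]
            p2y = nyp if a0 + 2 == i else pos[a0 + 2, 1]
            p2z = nzp if a0 + 2 == i else pos[a0 + 2, 2]
            b1x = p1x - p0x
            b1y = p1y - p0y
            b1z = p1z - p0z
            b2x = p2x - p1x
            b2y = p2y - p1y
            b2z = p2z - p1z
            c_new = (b1x * b2x + b1y * b2y + b1z * b2z) * \
                inv_len[b1x + OFF, b1y + OFF, b1z + OFF] * \
                inv_len[b2x + OFF, b2y + OFF, b2z + OFF]
            if form_flag == 0:
                dE += k * (c_old - c_new)
            else:
                dE += k * ((1.0 - c_new) ** 2 - (1.0 - c_old) ** 2)

        if dE > 0.0 and np.random.random() >= math.exp(-dE):
            continue

        # accept: update occupancy and position
        if cube_mode:
            for a in range(2):
                for b in range(2):
                    for c in range(2):
                        occ[(ox + a) & mask, (oy + b) & mask, (oz + c) & mask] = 0
            for a in range(2):
                for b in range(2):
                    for c in range(2):
                        occ[(nxp + a) & mask, (nyp + b) & mask, (nzp + c) & mask] = 1
        else:
            occ[ox & mask, oy & mask, oz & mask] = 0
            occ[nxp & mask, nyp & mask, nzp & mask] = 1
        pos[i, 0] = nxp
        pos[i, 1] = nyp
        pos[i, 2] = nzp
        energy += dE
        acc += 1
    return energy, acc
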