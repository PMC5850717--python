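"""Bit-packed Wright–Fisher engine (numba).

Haplotypes are rows of a (2N, W) uint64 matrix; each segregating
mutation occupies one bit slot (column ``slot`` lives in word
``slot >> 6``, bit ``slot & 63``).  Mutation follows the infinite-sites
model on continuous positions in [0, L); recombination is a single
crossover per meiosis at rate r·L.  Selection is overdominant viability
weighting at a single designated slot with genotype fitnesses
1 : 1+hs : 1+s (ancestral hom : het : derived hom).

Randomness comes from an inline xorshift128+ generator whose two-word
state is passed in explicitly, which keeps replicates bit-reproducible
and cheap (the per-gamete RNG cost dominates the generation loop).

Numba note: ``int()`` of a uint64 stays uint64 and unifies with int64
to float64, so indices derived from RNG words are cast through int64
explicitly.
"""

from __future__ import annotations

import numpy as np
from numba import int64, njit, uint64

U64 = uint64
I64 = int64
_INV53 = 1.0 / (1 << 53)

# kernel return codes
OK = 0
LOST = 1  # balanced allele lost or fixed
FULL = 2  # slot capacity exhausted (raise and retry with more words)


@njit(inline="always", cache=True)
def _next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << U64(23)
    s1 ^= s1 >> U64(17)
    s1 ^= s0
    s1 ^= s0 >> U64(26)
    state[1] = s1
    return state[0] + state[1]


@njit(inline="always", cache=True)
def _unif(state):
    return (_next(state) >> U64(11)) * _INV53


@njit(cache=True)
def evolve(
    popA,
    popB,
    positions,
    inuse,
    free_stack,
    n_free,
    gens,
    mu_total,
    rL,
    L,
    N,
    sel_slot,
    h,
    s,
    check_every,
    state,
    fixed_pos,
    n_fixed,
):
    """Evolve a population for ``gens`` generations in place.

    popA must hold the current generation on entry; popA/popB are used
    as alternating buffers.  Returns (status, n_free, buf, n_fixed)
    where buf says which buffer (0 = popA, 1 = popB) holds the final
    generation.  Mutations fixing in the whole population are recorded
    in ``fixed_pos`` and their slots recycled.
    """
    twoN = popA.shape[0]
    W = popA.shape[1]
    cap = positions.shape[0]
    grp = np.empty(N, np.int64)
    cur = popA
    nxt = popB
    buf = 0
    w_het = 1.0 + h * s
    w_hom = 1.0 + s
    for g in range(gens):
        n0 = 0
        n1 = 0
        n2 = 0
        if sel_slot >= 0:
            wq = sel_slot >> 6
            wb = U64(1) << U64(sel_slot & 63)
            for i in range(N):
                gt = 0
                if cur[2 * i, wq] & wb:
                    gt += 1
                if cur[2 * i + 1, wq] & wb:
                    gt += 1
                if gt == 0:
                    n0 += 1
                elif gt == 1:
                    n1 += 1
                else:
                    n2 += 1
            i0 = 0
            i1 = n0
            i2 = n0 + n1
            for i in range(N):
                gt = 0
                if cur[2 * i, wq] & wb:
                    gt += 1
                if cur[2 * i + 1, wq] & wb:
                    gt += 1
                if gt == 0:
                    grp[i0] = i
                    i0 += 1
                elif gt == 1:
                    grp[i1] = i
                    i1 += 1
                else:
                    grp[i2] = i
                    i2 += 1
        W0 = n0 * 1.0
        W1 = n1 * w_het
        W2 = n2 * w_hom
        Wtot = W0 + W1 + W2
        for k in range(twoN):
            r = _next(state)
            if sel_slot >= 0:
                u = _unif(state) * Wtot
                if u < W0:
                    par = grp[I64(_next(state) % U64(n0))]
                elif u < W0 + W1:
                    par = grp[n0 + I64(_next(state) % U64(n1))]
                else:
                    par = grp[n0 + n1 + I64(_next(state) % U64(n2))]
            else:
                par = I64(_next(state) % U64(N))
            hap = 2 * par + I64(r & U64(1))
            for w_ in range(W):
                nxt[k, w_] = cur[hap, w_]
            if ((r >> U64(11)) * _INV53) < rL:
                # single crossover at x: left of x from hap, right from the
                # parent's other haplotype
                other = 2 * par + 1 - I64(r & U64(1))
                x = _unif(state) * L
                for slot in range(cap):
                    if inuse[slot] and positions[slot] >= x:
                        wq2 = slot >> 6
                        wb2 = U64(1) << U64(slot & 63)
                        if cur[other, wq2] & wb2:
                            nxt[k, wq2] |= wb2
                        else:
                            nxt[k, wq2] &= ~wb2
        tmp = cur
        cur = nxt
        nxt = tmp
        buf = 1 - buf
        # new mutations: Poisson(2N·mu·L) by inversion
        nmut = 0
        t = np.exp(-mu_total)
        pacc = t
        u = _unif(state)
        while u > pacc:
            nmut += 1
            t *= mu_total / nmut
            pacc += t
        for _ in range(nmut):
            if n_free == 0:
                return FULL, n_free, buf, n_fixed
            n_free -= 1
            slot = free_stack[n_free]
            positions[slot] = _unif(state) * L
            inuse[slot] = True
            hap = I64(_next(state) % U64(twoN))
            cur[hap, slot >> 6] |= U64(1) << U64(slot & 63)
        # conditioning: the balanced polymorphism must survive
        if sel_slot >= 0:
            wq = sel_slot >> 6
            wb = U64(1) << U64(sel_slot & 63)
            cnt = 0
            for i in range(twoN):
                if cur[i, wq] & wb:
                    cnt += 1
            if cnt == 0 or cnt == twoN:
                return LOST, n_free, buf, n_fixed
        # recycle lost slots; record + recycle fixed ones
        if g % check_every == check_every - 1 or n_free < 8:
            for w_ in range(W):
                orall = U64(0)
                andall = ~U64(0)
                for i in range(twoN):
                    v = cur[i, w_]
                    orall |= v
                    andall &= v
                for b in range(64):
                    slot = (w_ << 6) + b
                    if slot >= cap or not inuse[slot] or slot == sel_slot:
                        continue
                    bit = U64(1) << U64(b)
                    if not (orall & bit):
                        inuse[slot] = False
                        free_stack[n_free] = slot
                        n_free += 1
                    elif andall & bit:
                        fixed_pos[n_fixed] = positions[slot]
                        n_fixed += 1
                        nb = ~bit
                        for i in range(twoN):
                            cur[i, w_] &= nb
                        inuse[slot] = False
                        free_stack[n_free] = slot
                        n_free += 1
    return OK, n_free, buf, n_fixed


def unpack_columns(pop: np.ndarray, rows: np.ndarray, slots: np.ndarray) -> np.ndarray:
    """Derived-allele counts at the given slots among the given rows."""
    sub = pop[rows]
    bits = np.unpackbits(sub.view(np.uint8), axis=1, bitorder="little")
    return bits[:, slots].sum(axis=0).astype(np.int64)


def row_bits(pop: np.ndarray, row: int, slots: np.ndarray) -> np.ndarray:
    """Boolean derived-allele state of one haplotype at the given slots."""
    bits = np.unpackbits(pop[row : row + 1].view(np.uint8), axis=1, bitorder="little")
    return bits[0, slots].astype(bool)
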