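"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (exhaustive
enumeration, exact integer arithmetic) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache

import numpy as np


# -- perfect phylogeny: enumerate all rooted mutation trees -------------------

@lru_cache(maxsize=None)
def rooted_forests(n_mut: int) -> tuple:
    """All acyclic parent vectors over n mutations (parent -1 = root).

    Returns tuples (parents, pathmasks) where pathmasks[m] is the bitmask
    of mutation m plus all its ancestors.
    """
    out = []
    for parents in itertools.product(range(-1, n_mut), repeat=n_mut):
        if any(parents[m] == m for m in range(n_mut)):
            continue
        pathmasks = [None] * n_mut
        ok = True
        for m in range(n_mut):
            seen = set()
            cur = m
            while cur != -1:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = parents[cur]
            if not ok:
                break
            mask = 0
            cur = m
            while cur != -1:
                mask |= 1 << cur
                cur = parents[cur]
            pathmasks[m] = mask
        if ok:
            out.append((parents, tuple(pathmasks)))
    return tuple(out)


def observed_parent_maps(observed_masks: set[int], n_mut: int) -> set[frozenset]:
    """Brute-force containment enumeration.

    For every rooted mutation tree whose root-path sets cover all
    observed presence signatures, derive the observed-clone parent map
    (each observed signature -> nearest observed ancestor signature, or
    None).  Returns the set of distinct maps over all valid trees (a
    conflict-free matrix should yield exactly one).
    """
    nonzero = frozenset(m for m in observed_masks if m != 0)
    has_root_clone = 0 in observed_masks
    maps = set()
    for parents, pathmasks in rooted_forests(n_mut):
        pathset = frozenset(pathmasks)
        if not nonzero <= pathset:
            continue
        node_of = {pathmasks[m]: m for m in range(n_mut)}
        entries = []
        if has_root_clone:
            entries.append((0, None))
        for c in nonzero:
            cur = parents[node_of[c]]
            parent_mask = None
            while cur != -1:
                if pathmasks[cur] in nonzero:
                    parent_mask = pathmasks[cur]
                    break
                cur = parents[cur]
            if parent_mask is None and has_root_clone:
                parent_mask = 0
            entries.append((c, parent_mask))
        maps.add(frozenset(entries))
    return maps


# -- exhaustive minimum-flip search -------------------------------------------

def _columns_conflict_free(cols: list[int], full: int) -> bool:
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            if a & b and a & ~b & full and b & ~a & full:
                return False
    return True


def exhaustive_min_flips(presence: np.ndarray, max_k: int) -> int | None:
    """Smallest number of presence-call flips reaching conflict-freeness.

    Pure exhaustive search over all flip sets of size 0..max_k.
    """
    n_cells, n_mut = presence.shape
    full = (1 << n_cells) - 1
    base = [int(sum(1 << c for c in range(n_cells) if presence[c, j])) for j in range(n_mut)]
    positions = [(c, j) for c in range(n_cells) for j in range(n_mut)]
    for k in range(max_k + 1):
        for combo in itertools.combinations(positions, k):
            cols = list(base)
            for c, j in combo:
                cols[j] ^= 1 << c
            if _columns_conflict_free(cols, full):
                return k
    return None


# -- Fisher exact 2x2 by exact integer enumeration ----------------------------

def fisher_2x2_exact_p(table) -> Fraction:
    """Two-sided point-probability p as an exact rational.

    Enumerates every table with the observed margins; table weights are
    the exact integer products of binomial coefficients.
    """
    (a, b), (c, d) = table
    r1, c1 = a + b, a + c
    n = a + b + c + d
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return Fraction(1)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    weights = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(num, sum(weights.values()))


# -- Freeman-Halton 2x3 by exact integer enumeration --------------------------

def freeman_halton_2x3_exact_p(row1, row2) -> Fraction:
    r1 = [int(x) for x in row1]
    cols = [int(a + b) for a, b in zip(row1, row2)]
    n1 = sum(r1)
    w_obs = math.prod(math.comb(c, k) for c, k in zip(cols, r1))
    num = den = 0
    for x0 in range(0, min(cols[0], n1) + 1):
        for x1 in range(0, min(cols[1], n1 - x0) + 1):
            x2 = n1 - x0 - x1
            if x2 < 0 or x2 > cols[2]:
                continue
            w = math.comb(cols[0], x0) * math.comb(cols[1], x1) * math.comb(cols[2], x2)
            den += w
            if w <= w_obs:
                num += w
    return Fraction(num, den)
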