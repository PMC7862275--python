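"""Mutation acquisition order, perfect-phylogeny checks/repair, clone trees.

The clonal model is a perfect phylogeny with wild-type ancestral state:
each panel mutation is gained exactly once (WT->HET) and never lost, and
zygosity may escalate (HET->HOM) but never revert.  Under this model the
presence/absence patterns of any two mutations across cells can show at
most two of the three informative pair patterns {(1,1), (1,0), (0,1)};
a pair showing all three is a *conflict* (the two-character analogue of
the four-gamete test rooted at all-zero).

``build_clone_tree`` uses the classic containment construction: sort
mutations by mutated-cell frequency (the acquisition-order surrogate:
under no back-mutation, an earlier mutation is carried by a superset of
cells), then thread each clone's presence signature through a prefix
trie from the root; conflict-freeness guarantees the result is the
unique perfect phylogeny.  At zygosity resolution, clones sharing a
presence signature are expanded along single HET->HOM escalation steps,
materializing unobserved intermediates so that every edge is exactly one
event.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clone_calling import ClonePartition
from .genotype_io import GenotypeMatrix, GenotypeState

logger = logging.getLogger(__name__)

__all__ = [
    "MutationOrder",
    "ConflictPair",
    "ConflictReport",
    "CloneNode",
    "CloneTree",
    "RepairError",
    "order_mutations",
    "find_conflicts",
    "repair_min_flips",
    "build_clone_tree",
    "export_newick",
    "parse_newick",
]


# -- mutation acquisition order -------------------------------------------

@dataclass
class MutationOrder:
    """Mutations ranked by pooled mutated-cell fraction, descending."""

    ranked_ids: list[str]
    fractions: dict[str, float]

    def rank(self, mutation_id: str) -> int:
        return self.ranked_ids.index(mutation_id)


def order_mutations(m: GenotypeMatrix) -> MutationOrder:
    """Rank mutations by mutated fraction over all cells (pooled).

    Ties are broken by the first-timepoint fraction, then by catalog
    order, making the ranking deterministic and invariant under row
    permutations of the matrix.
    """
    first_tp = m.timepoint_order[0] if m.timepoint_order else None

    def _fraction(col: np.ndarray) -> float:
        defined = col != GenotypeState.MISSING
        n = int(defined.sum())
        return float((col[defined] >= GenotypeState.HET).sum() / n) if n else 0.0

    pooled = {mid: _fraction(m.calls[:, j]) for j, mid in enumerate(m.mutation_ids)}
    tp_mask = m.timepoint_mask(first_tp) if first_tp else np.ones(m.n_cells, bool)
    first = {mid: _fraction(m.calls[tp_mask, j]) for j, mid in enumerate(m.mutation_ids)}
    catalog_pos = {mid: j for j, mid in enumerate(m.mutation_ids)}
    ranked = sorted(
        m.mutation_ids, key=lambda mid: (-pooled[mid], -first[mid], catalog_pos[mid])
    )
    return MutationOrder(ranked_ids=ranked, fractions=pooled)


# -- pairwise compatibility -----------------------------------------------

@dataclass(frozen=True)
class ConflictPair:
    mutation_i: str
    mutation_j: str
    n11: int
    n10: int
    n01: int


@dataclass
class ConflictReport:
    pairs: list[ConflictPair]

    @property
    def is_conflict_free(self) -> bool:
        return not self.pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs]) if self.pairs else pd.DataFrame(
            columns=["mutation_i", "mutation_j", "n11", "n10", "n01"]
        )


def _pair_counts(presence: np.ndarray, i: int, j: int) -> tuple[int, int, int]:
    """Witness pattern counts over cells where both columns are defined."""
    a, b = presence[:, i], presence[:, j]
    both = (a >= 0) & (b >= 0)
    a, b = a[both], b[both]
    return int(((a == 1) & (b == 1)).sum()), int(((a == 1) & (b == 0)).sum()), int(
        ((a == 0) & (b == 1)).sum()
    )


def _conflicting_pairs(presence: np.ndarray) -> list[tuple[int, int, int, int, int]]:
    out = []
    n_mut = presence.shape[1]
    for i, j in itertools.combinations(range(n_mut), 2):
        n11, n10, n01 = _pair_counts(presence, i, j)
        if n11 > 0 and n10 > 0 and n01 > 0:
            out.append((i, j, n11, n10, n01))
    return out


def find_conflicts(m: GenotypeMatrix) -> ConflictReport:
    """Report every mutation pair exhibiting all three witness patterns."""
    pres = m.presence()
    pairs = [
        ConflictPair(m.mutation_ids[i], m.mutation_ids[j], n11, n10, n01)
        for i, j, n11, n10, n01 in _conflicting_pairs(pres)
    ]
    return ConflictReport(pairs=pairs)


# -- minimum-flip repair ----------------------------------------------------

class RepairError(ValueError):
    """No conflict-free solution within the flip budget."""


def _first_conflict(presence: np.ndarray, rank_of: list[int]) -> tuple[int, int] | None:
    """First conflicting column pair, ordered by mutation rank."""
    cols = sorted(range(presence.shape[1]), key=lambda c: rank_of[c])
    for i, j in itertools.combinations(cols, 2):
        n11, n10, n01 = _pair_counts(presence, i, j)
        if n11 and n10 and n01:
            return i, j
    return None


def _exact_min_flips(
    presence: np.ndarray, rank_of: list[int], budget: int | None
) -> list[tuple[int, int]] | None:
    """Iterative-deepening branch and bound; provably minimal flip set.

    Branch rule: any conflict-free solution must differ from the current
    matrix at some defined position in the two columns of any currently
    conflicting pair, so branching over those positions is complete.
    """
    max_depth = presence.size if budget is None else budget

    def search(pres: np.ndarray, depth: int, flipped: frozenset) -> list[tuple[int, int]] | None:
        pair = _first_conflict(pres, rank_of)
        if pair is None:
            return []
        if depth == 0:
            return None
        i, j = pair
        cols = sorted((i, j), key=lambda c: rank_of[c])
        for c in range(pres.shape[0]):
            for col in cols:
                if pres[c, col] < 0 or (c, col) in flipped:
                    continue
                pres[c, col] ^= 1
                sub = search(pres, depth - 1, flipped | {(c, col)})
                pres[c, col] ^= 1
                if sub is not None:
                    return [(c, col)] + sub
        return None

    for depth in range(0, max_depth + 1):
        result = search(presence.copy(), depth, frozenset())
        if result is not None:
            return result
    return None


def _greedy_flips(
    presence: np.ndarray, rank_of: list[int], budget: int | None
) -> list[tuple[int, int]] | None:
    """Minority-class merge greedy for large instances (may exceed minimum).

    Resolve the first conflicting pair (by rank) by flipping one call
    from its smallest witness class, merging the cell into the dominant
    nested pattern; deterministic ties by cell order then mutation rank.
    """
    pres = presence.copy()
    flips: list[tuple[int, int]] = []
    flipped: set[tuple[int, int]] = set()
    limit = pres.size if budget is None else budget
    while True:
        pair = _first_conflict(pres, rank_of)
        if pair is None:
            return flips
        if len(flips) >= limit:
            return None
        i, j = pair
        hi, lo = sorted((i, j), key=lambda c: rank_of[c])  # hi = more frequent
        a, b = pres[:, hi], pres[:, lo]
        both = (a >= 0) & (b >= 0)
        classes = {
            # pattern (hi, lo) -> (cells, position to flip, new value direction)
            (0, 1): (np.flatnonzero(both & (a == 0) & (b == 1)), hi),  # gain hi -> (1,1)
            (1, 0): (np.flatnonzero(both & (a == 1) & (b == 0)), lo),  # gain lo -> (1,1)
            (1, 1): (np.flatnonzero(both & (a == 1) & (b == 1)), lo),  # drop lo -> (1,0)
        }
        order = [(0, 1), (1, 0), (1, 1)]
        chosen = None
        for pat in sorted(order, key=lambda p: (len(classes[p][0]), order.index(p))):
            cells, col = classes[pat]
            for c in cells:
                if (int(c), col) not in flipped:
                    chosen = (int(c), col)
                    break
            if chosen:
                break
        if chosen is None:
            return None  # every candidate already flipped once; give up
        c, col = chosen
        pres[c, col] ^= 1
        flipped.add(chosen)
        flips.append(chosen)


def repair_min_flips(
    m: GenotypeMatrix,
    budget: int | None = None,
    *,
    exact_limit: tuple[int, int] = (6, 30),
) -> tuple[GenotypeMatrix, list[tuple[str, str, str, str]]]:
    """Return a conflict-free matrix obtained by flipping presence calls.

    For instances within ``exact_limit`` (mutations, cells) the flip
    count is exactly minimal (iterative-deepening branch and bound);
    larger instances use the deterministic greedy, which may exceed the
    minimum.  A gained call becomes HET; a removed call becomes WT.

    Raises :class:`RepairError` when no conflict-free solution exists
    within ``budget`` flips.
    """
    if budget is not None and budget < 0:
        raise ValueError("budget must be >= 0")
    order = order_mutations(m)
    rank_of = [order.rank(mid) for mid in m.mutation_ids]
    presence = m.presence()
    small = m.n_mutations <= exact_limit[0] and m.n_cells <= exact_limit[1]
    flips = (
        _exact_min_flips(presence, rank_of, budget)
        if small
        else _greedy_flips(presence, rank_of, budget)
    )
    if flips is None:
        raise RepairError(
            f"no conflict-free solution within budget={budget} "
            f"({'exact' if small else 'greedy'} search)"
        )
    repaired = m.copy()
    flip_records = []
    for c, col in flips:
        old = GenotypeState(int(repaired.calls[c, col]))
        new = GenotypeState.HET if old == GenotypeState.WT else GenotypeState.WT
        repaired.calls[c, col] = new
        flip_records.append((m.cells[c], m.mutation_ids[col], old.name, new.name))
    if flip_records:
        logger.info("repaired %d call(s): %s", len(flip_records), flip_records[:10])
    return repaired, flip_records


# -- clone tree --------------------------------------------------------------

@dataclass
class CloneNode:
    """One node of a clone tree.

    ``signature`` maps mutation id -> state name at the tree's
    resolution ("MUT" for presence trees).  Inferred (unobserved)
    intermediate nodes have ``observed=False`` and size 0.
    """

    name: str
    signature: dict[str, str]
    observed: bool = True
    size: int = 0
    event: str | None = None  # label of the edge from the parent
    children: list["CloneNode"] = field(default_factory=list)
    parent: "CloneNode | None" = field(default=None, repr=False, compare=False)

    def add_child(self, child: "CloneNode") -> "CloneNode":
        child.parent = self
        self.children.append(child)
        return child


@dataclass
class CloneTree:
    """Rooted clone tree with single-event edges."""

    root: CloneNode
    resolution: str

    def nodes(self) -> list[CloneNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def edges(self) -> list[tuple[CloneNode, CloneNode]]:
        return [(n, c) for n in self.nodes() for c in n.children]

    def find(self, name: str) -> CloneNode:
        for n in self.nodes():
            if n.name == name:
                return n
        raise KeyError(name)

    def observed_parent_map(self) -> dict[str, str | None]:
        """Each observed node -> its nearest observed ancestor (or None)."""
        out: dict[str, str | None] = {}
        for n in self.nodes():
            if not n.observed:
                continue
            p = n.parent
            while p is not None and not p.observed:
                p = p.parent
            out[n.name] = p.name if p is not None else None
        return out

    def topology(self) -> tuple:
        """Canonical nested form for isomorphism comparison (sibling-order free)."""

        def canon(n: CloneNode) -> tuple:
            sig = tuple(sorted(n.signature.items()))
            return (sig, n.observed, tuple(sorted(canon(c) for c in n.children)))

        return canon(self.root)

    def to_json_dict(self) -> dict:
        nodes = [
            {
                "name": n.name,
                "observed": n.observed,
                "size": n.size,
                "signature": n.signature,
            }
            for n in self.nodes()
        ]
        edges = [
            {"parent": p.name, "child": c.name, "event": c.event} for p, c in self.edges()
        ]
        return {"resolution": self.resolution, "nodes": nodes, "edges": edges}


def _presence_sets(p: ClonePartition) -> dict[tuple[int, ...], frozenset[str]]:
    """Clone signature tuple -> presence set of mutation ids."""
    out = {}
    for c in p.clones:
        out[c.signature] = frozenset(
            mid for mid, s in zip(p.mutation_ids, c.signature) if s > 0
        )
    return out


def build_clone_tree(
    p: ClonePartition, order: MutationOrder, *, include_minor: bool = True
) -> CloneTree:
    """Perfect-phylogeny containment construction over a clone partition.

    Mutations are threaded in rank order; each clone sits under the clone
    whose presence signature is its immediate subset, with unobserved
    intermediate signatures materialized as inferred nodes.  At zygosity
    resolution each presence node is expanded along HET->HOM escalation
    steps (intermediates always materialized, so every edge is exactly
    one event).  Sibling order follows mutation rank.

    Raises ``ValueError`` when the presence signatures conflict — repair
    the matrix first.
    """
    clones = [c for c in p.clones if include_minor or not c.minor]
    if not clones:
        raise ValueError("no clones to build a tree from")
    rank_of = {mid: order.rank(mid) for mid in p.mutation_ids}

    # conflict check on the clone signatures
    sig_presence = np.array(
        [[1 if s > 0 else 0 for s in c.signature] for c in clones], dtype=np.int8
    )
    conflicts = _conflicting_pairs(sig_presence)
    if conflicts:
        i, j, *_ = conflicts[0]
        raise ValueError(
            f"presence signatures conflict (e.g. pair {p.mutation_ids[i]}, "
            f"{p.mutation_ids[j]}); run repair_min_flips first"
        )

    # group clones by presence set
    by_presence: dict[frozenset[str], list] = {}
    for c in clones:
        pres = frozenset(mid for mid, s in zip(p.mutation_ids, c.signature) if s > 0)
        by_presence.setdefault(pres, []).append(c)

    def presence_name(pres: frozenset[str]) -> str:
        if not pres:
            return "root"
        return "anc_" + "_".join(sorted(pres, key=lambda m: rank_of[m]))

    def base_signature(pres: frozenset[str]) -> dict[str, str]:
        return {mid: ("HET" if mid in pres else "WT") for mid in p.mutation_ids}

    def presence_signature(pres: frozenset[str]) -> dict[str, str]:
        return {mid: ("MUT" if mid in pres else "WT") for mid in p.mutation_ids}

    # prefix trie over rank-sorted presence sets
    root_pres: frozenset[str] = frozenset()
    trie_nodes: dict[frozenset[str], CloneNode] = {}

    def make_presence_node(pres: frozenset[str], event: str | None) -> CloneNode:
        obs_clones = by_presence.get(pres, [])
        if p.resolution == "presence" and obs_clones:
            c = obs_clones[0]
            node = CloneNode(
                name=c.label,
                signature=presence_signature(pres),
                observed=True,
                size=c.size,
                event=event,
            )
        else:
            node = CloneNode(
                name=presence_name(pres),
                signature=(
                    presence_signature(pres) if p.resolution == "presence" else base_signature(pres)
                ),
                observed=False,
                size=0,
                event=event,
            )
        return node

    trie_nodes[root_pres] = make_presence_node(root_pres, None)
    # insert presence sets in (size, rank-path) order so prefixes come first
    all_pres = sorted(
        by_presence, key=lambda s: (len(s), tuple(sorted(rank_of[m] for m in s)))
    )
    for pres in all_pres:
        path = sorted(pres, key=lambda m: rank_of[m])
        current = root_pres
        for mut in path:
            nxt = current | {mut}
            if nxt not in trie_nodes:
                node = make_presence_node(nxt, f"+{mut}")
                trie_nodes[current].add_child(node)
                trie_nodes[nxt] = node
            current = nxt

    # verify containment (every clone reached its own node)
    for pres in all_pres:
        if pres not in trie_nodes:
            raise ValueError(f"could not place presence signature {sorted(pres)}")

    if p.resolution == "zygosity":
        # expand each presence node along HET->HOM escalation steps
        state_name = {0: "WT", 1: "HET", 2: "HOM"}
        for pres, entry in list(trie_nodes.items()):
            obs_clones = by_presence.get(pres, [])
            variants: dict[frozenset[str], CloneNode] = {frozenset(): entry}
            # observed variant with empty HOM set replaces the entry in place
            items = []
            for c in obs_clones:
                hom = frozenset(
                    mid for mid, s in zip(p.mutation_ids, c.signature) if s == GenotypeState.HOM
                )
                items.append((hom, c))
            for hom, c in sorted(
                items, key=lambda hc: (len(hc[0]), tuple(sorted(rank_of[m] for m in hc[0])))
            ):
                if hom == frozenset():
                    entry.name, entry.observed, entry.size = c.label, True, c.size
                    continue
                # attach under the existing variant with the largest subset HOM set
                anc = max(
                    (h for h in variants if h < hom),
                    key=lambda h: (len(h), tuple(sorted(-rank_of[m] for m in h))),
                )
                current = anc
                for mut in sorted(hom - anc, key=lambda m2: rank_of[m2]):
                    nxt = current | {mut}
                    if nxt not in variants:
                        sig = dict(base_signature(pres))
                        for m2 in nxt:
                            sig[m2] = "HOM"
                        is_target = nxt == hom
                        node = CloneNode(
                            name=c.label if is_target else presence_name(pres) + "__hom_"
                            + "_".join(sorted(nxt, key=lambda m3: rank_of[m3])),
                            signature=sig,
                            observed=is_target,
                            size=c.size if is_target else 0,
                            event=f"{mut}:HET>HOM",
                        )
                        variants[current].add_child(node)
                        variants[nxt] = node
                    current = nxt

    # sibling order: gains by mutation rank, then escalations by rank
    def sort_children(n: CloneNode) -> None:
        def key(c: CloneNode) -> tuple:
            ev = c.event or ""
            if ev.startswith("+"):
                return (0, rank_of.get(ev[1:], 99))
            return (1, rank_of.get(ev.split(":")[0], 99))

        n.children.sort(key=key)
        for c in n.children:
            sort_children(c)

    root = trie_nodes[root_pres]
    # drop an unobserved all-wild-type root with a single child
    if not root.observed and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.event = None
    sort_children(root)
    return CloneTree(root=root, resolution=p.resolution)


# -- Newick export / parse ---------------------------------------------------

def export_newick(t: CloneTree) -> str:
    """Newick with labels on all nodes and event labels in comments."""

    def render(n: CloneNode) -> str:
        label = n.name
        comment = f"[&event={n.event}]" if n.event else ""
        if n.children:
            inner = ",".join(render(c) for c in n.children)
            return f"({inner}){label}{comment}"
        return f"{label}{comment}"

    return render(t.root) + ";"


def parse_newick(text: str) -> CloneTree:
    """Parse the package's Newick dialect (labels + [&event=...] comments)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> CloneNode:
        nonlocal pos
        children: list[CloneNode] = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                children.append(parse_node())
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
        start = pos
        while pos < len(s) and s[pos] not in "(),[":
            pos += 1
        label = s[start:pos]
        event = None
        if pos < len(s) and s[pos] == "[":
            end = s.index("]", pos)
            comment = s[pos + 1 : end]
            if comment.startswith("&event="):
                event = comment[len("&event=") :]
            pos = end + 1
        node = CloneNode(name=label, signature={}, observed=True, event=event)
        for c in children:
            node.add_child(c)
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters after position {pos}")
    return CloneTree(root=root, resolution="unknown")
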