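"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from clonalarch.genotype_io import GenotypeMatrix, GenotypeState, Mutation
from clonalarch.phylogeny import CloneNode, CloneTree
from clonalarch.synthetic import SimulationConfig

_CODE = {"WT": 0, "HET": 1, "HOM": 2, "NA": -1, "MUT": 1}


def make_matrix(
    rows: list[tuple[str, str, list[str]]],
    mutation_ids: list[str],
    timepoint_order: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a matrix from (cell_id, timepoint, [state tokens]) rows."""
    return GenotypeMatrix(
        cells=[r[0] for r in rows],
        timepoints=[r[1] for r in rows],
        mutations=[Mutation(id=m) for m in mutation_ids],
        calls=np.array([[_CODE[s] for s in r[2]] for r in rows], dtype=np.int8),
        timepoint_order=timepoint_order or [],
    )


def presence_to_matrix(presence: np.ndarray, timepoint: str = "T1") -> GenotypeMatrix:
    """Presence/absence array -> matrix with HET for present calls."""
    n_cells, n_mut = presence.shape
    return GenotypeMatrix(
        cells=[f"c{i:03d}" for i in range(n_cells)],
        timepoints=[timepoint] * n_cells,
        mutations=[Mutation(id=f"M{j}") for j in range(n_mut)],
        calls=presence.astype(np.int8),
    )


def random_conflict_free_presence(
    rng: np.random.Generator, n_mut: int, n_cells: int
) -> np.ndarray:
    """Random presence matrix generated from a random mutation tree.

    Mutations are threaded on a random rooted forest; every cell's
    signature is a root-path set, so the matrix is conflict-free by
    construction.
    """
    order = rng.permutation(n_mut)
    parent: dict[int, int] = {}
    for pos, m in enumerate(order):
        choices = [-1] + list(order[:pos])
        parent[int(m)] = int(rng.choice(choices))
    pathset = {}
    for m in range(n_mut):
        mask = np.zeros(n_mut, dtype=np.int8)
        cur = m
        while cur != -1:
            mask[cur] = 1
            cur = parent[cur]
        pathset[m] = mask
    candidates = [np.zeros(n_mut, dtype=np.int8)] + [pathset[m] for m in range(n_mut)]
    picks = rng.integers(0, len(candidates), size=n_cells)
    return np.stack([candidates[k] for k in picks])


def truth_tree(cfg: SimulationConfig) -> CloneTree:
    """The clone tree a perfect reconstruction should recover."""
    nodes = {}
    for c in cfg.clones:
        sig = {m.id: c.signature.get(m.id, "WT") for m in cfg.mutations}
        nodes[c.id] = CloneNode(name=c.id, signature=sig, observed=True)
    root = None
    for c in cfg.clones:
        if c.parent is None:
            root = nodes[c.id]
        else:
            nodes[c.parent].add_child(nodes[c.id])
    return CloneTree(root=root, resolution="zygosity")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
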