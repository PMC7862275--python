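"""Partition cells into clones by genotype signature; per-timepoint frequencies.

A clone is the set of cells sharing an identical mutation signature,
either at *zygosity* resolution (WT/HET/HOM distinguished) or at
*presence* resolution (HET and HOM collapse to "mutated").  Cells with
MISSING calls join a clone only when exactly one clone is compatible
with their defined calls; otherwise they are set aside as unassigned and
reported, never silently dropped.

The mutated fraction of a variant at a timepoint is the proportion of
mutated cells (heterozygous or homozygous) among cells with a defined
call, mirroring how single-cell mutational frequencies are tabulated in
clonal-evolution studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, GenotypeState

logger = logging.getLogger(__name__)

__all__ = [
    "Clone",
    "ClonePartition",
    "FrequencyRecord",
    "call_clones",
    "mutated_fraction",
    "zygosity_distribution",
    "clone_entropy",
]


def _clone_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... deterministic clone labels."""
    labels = []
    for i in range(n):
        s, k = "", i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


@dataclass
class Clone:
    """One clone: a signature and its member cells."""

    label: str
    signature: tuple[int, ...]  # GenotypeState codes at the partition's resolution
    cells: list[str]
    timepoint_counts: dict[str, int]
    minor: bool = False

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass
class ClonePartition:
    """Grouping of cells into clones at one resolution."""

    resolution: str  # "presence" or "zygosity"
    mutation_ids: list[str]
    clones: list[Clone]
    unassigned: list[str]
    timepoint_order: list[str]
    n_cells: int

    def signature_of(self, label: str) -> tuple[int, ...]:
        return next(c.signature for c in self.clones if c.label == label)

    def clone_of_signature(self, signature: tuple[int, ...]) -> Clone:
        for c in self.clones:
            if c.signature == tuple(signature):
                return c
        raise KeyError(f"no clone with signature {signature}")

    @property
    def n_assigned(self) -> int:
        return sum(c.size for c in self.clones)

    def major_only(self) -> "ClonePartition":
        """Copy with minor clones removed; their cells become unassigned."""
        majors = [c for c in self.clones if not c.minor]
        dropped = [cell for c in self.clones if c.minor for cell in c.cells]
        return ClonePartition(
            resolution=self.resolution,
            mutation_ids=list(self.mutation_ids),
            clones=majors,
            unassigned=self.unassigned + dropped,
            timepoint_order=list(self.timepoint_order),
            n_cells=self.n_cells,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clones:
            sig = "/".join(
                f"{m}:{GenotypeState(s).name}" if self.resolution == "zygosity" else m
                for m, s in zip(self.mutation_ids, c.signature)
                if s > 0
            )
            rows.append(
                {
                    "clone": c.label,
                    "signature": sig or "(none)",
                    "size": c.size,
                    "minor": c.minor,
                    **{f"n_{tp}": c.timepoint_counts.get(tp, 0) for tp in self.timepoint_order},
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FrequencyRecord:
    """Zygosity distribution of one mutation at one timepoint."""

    mutation_id: str
    timepoint: str
    counts: dict[str, int]  # over WT/HET/HOM/MISSING
    proportions: dict[str, float]  # over all cells of the timepoint
    defined_proportions: dict[str, float]  # renormalized over non-MISSING
    mutated_fraction: float

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"zygosity proportions sum to {total}")


def call_clones(
    m: GenotypeMatrix, resolution: str = "zygosity", min_cells: int = 1
) -> ClonePartition:
    """Group cells by exact signature at the chosen resolution.

    Clones smaller than ``min_cells`` are retained but flagged minor.
    Cells containing MISSING calls are assigned by exact match on their
    defined positions when a unique clone is compatible; otherwise they
    are reported as unassigned.
    """
    if resolution not in ("presence", "zygosity"):
        raise ValueError("resolution must be 'presence' or 'zygosity'")
    if m.n_cells == 0:
        raise ValueError("empty genotype matrix")
    calls = m.presence() if resolution == "presence" else m.calls
    defined = calls != GenotypeState.MISSING
    full = defined.all(axis=1)

    groups: dict[tuple[int, ...], list[int]] = {}
    for i in np.flatnonzero(full):
        groups.setdefault(tuple(int(v) for v in calls[i]), []).append(int(i))

    # cells with MISSING positions: unique compatible clone, else unassigned
    unassigned_idx: list[int] = []
    for i in np.flatnonzero(~full):
        mask = defined[i]
        compatible = [
            sig for sig in groups if np.array_equal(np.asarray(sig)[mask], calls[i][mask])
        ]
        if len(compatible) == 1:
            groups[compatible[0]].append(int(i))
        else:
            unassigned_idx.append(int(i))
    if unassigned_idx:
        logger.info(
            "%d cell(s) with missing calls left unassigned (0 or >1 compatible clones)",
            len(unassigned_idx),
        )

    # deterministic clone order: size desc, then signature
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    labels = _clone_labels(len(ordered))
    clones = []
    for label, (sig, idx) in zip(labels, ordered):
        tp_counts: dict[str, int] = {}
        for i in idx:
            tp_counts[m.timepoints[i]] = tp_counts.get(m.timepoints[i], 0) + 1
        clones.append(
            Clone(
                label=label,
                signature=sig,
                cells=[m.cells[i] for i in sorted(idx)],
                timepoint_counts=tp_counts,
                minor=len(idx) < min_cells,
            )
        )
    return ClonePartition(
        resolution=resolution,
        mutation_ids=list(m.mutation_ids),
        clones=clones,
        unassigned=[m.cells[i] for i in unassigned_idx],
        timepoint_order=list(m.timepoint_order),
        n_cells=m.n_cells,
    )


def mutated_fraction(m: GenotypeMatrix, mutation_id: str, timepoint: str | None = None) -> float:
    """(#HET + #HOM) / #non-MISSING among cells of the timepoint.

    ``timepoint=None`` pools all cells.
    """
    j = m.mutation_index(mutation_id)
    col = m.calls[:, j]
    if timepoint is not None:
        col = col[m.timepoint_mask(timepoint)]
    defined = col != GenotypeState.MISSING
    n = int(defined.sum())
    if n == 0:
        raise ValueError(
            f"no defined calls for {mutation_id}"
            + (f" at {timepoint}" if timepoint else "")
        )
    return float((col[defined] >= GenotypeState.HET).sum() / n)


def zygosity_distribution(m: GenotypeMatrix, mutation_id: str, timepoint: str) -> FrequencyRecord:
    """Proportions over {WT, HET, HOM, MISSING} among cells of a timepoint."""
    j = m.mutation_index(mutation_id)
    col = m.calls[m.timepoint_mask(timepoint), j]
    total = len(col)
    counts = {s.name: int((col == s).sum()) for s in GenotypeState}
    defined_total = total - counts["MISSING"]
    if defined_total == 0:
        raise ValueError(f"no defined calls for {mutation_id} at {timepoint}")
    proportions = {k: v / total for k, v in counts.items()}
    defined_proportions = {
        k: counts[k] / defined_total for k in ("WT", "HET", "HOM")
    }
    return FrequencyRecord(
        mutation_id=mutation_id,
        timepoint=timepoint,
        counts=counts,
        proportions=proportions,
        defined_proportions=defined_proportions,
        mutated_fraction=defined_proportions["HET"] + defined_proportions["HOM"],
    )


def clone_entropy(p: ClonePartition, timepoint: str | None = None) -> float:
    """Shannon entropy (natural log) of the clone-size distribution.

    A scale-free summary of clonal heterogeneity; computed over assigned
    cells, optionally restricted to one timepoint.
    """
    if timepoint is None:
        sizes = np.array([c.size for c in p.clones], dtype=float)
    else:
        sizes = np.array([c.timepoint_counts.get(timepoint, 0) for c in p.clones], dtype=float)
    sizes = sizes[sizes > 0]
    if sizes.size == 0:
        return math.nan
    q = sizes / sizes.sum()
    return float(-(q * np.log(q)).sum())
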