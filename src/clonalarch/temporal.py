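"""Clone and mutation dynamics across timepoints (fishplot-ready tables).

Clones are matched across timepoints by exact signature: a clone that
changes zygosity is a different clone.  For every clone and timepoint we
emit

* ``own_fraction``   — cells with exactly that signature / assigned
  cells of the timepoint, and
* ``nested_fraction`` — own fraction plus all descendants', the nested
  prevalence a fishplot/timescape layout consumes.

Nested fractions are computed bottom-up, so parent >= child holds by
construction; the proportional rescaling helper is applied defensively
(and logged) wherever externally supplied nested values violate nesting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clone_calling import ClonePartition, FrequencyRecord, mutated_fraction, zygosity_distribution
from .genotype_io import GenotypeMatrix
from .phylogeny import CloneTree, CloneNode, MutationOrder

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceTable",
    "TrajectoryTable",
    "rescale_children",
    "track_clones",
    "frequency_trajectories",
    "zygosity_evolution",
    "timescape_records",
]


@dataclass
class PrevalenceTable:
    """Per-clone, per-timepoint own and nested prevalences."""

    frame: pd.DataFrame  # columns: clone, parent, timepoint, own_fraction, nested_fraction
    timepoint_order: list[str]

    def own(self, clone: str, timepoint: str) -> float:
        sel = (self.frame["clone"] == clone) & (self.frame["timepoint"] == timepoint)
        return float(self.frame.loc[sel, "own_fraction"].iloc[0])

    def nested(self, clone: str, timepoint: str) -> float:
        sel = (self.frame["clone"] == clone) & (self.frame["timepoint"] == timepoint)
        return float(self.frame.loc[sel, "nested_fraction"].iloc[0])


@dataclass
class TrajectoryTable:
    """Per-mutation mutated fractions through time plus acquisition rank."""

    frame: pd.DataFrame  # columns: mutation, rank, one column per timepoint
    timepoint_order: list[str]

    def fraction(self, mutation_id: str, timepoint: str) -> float:
        row = self.frame.loc[self.frame["mutation"] == mutation_id]
        return float(row[timepoint].iloc[0])


def rescale_children(parent_nested: float, children_nested: Sequence[float]) -> list[float]:
    """Proportionally shrink children so their sum fits inside the parent.

    Fishplot nesting requires sum(children) <= parent; sampling noise can
    violate it.  Children are scaled by ``parent / sum(children)`` (only
    when the sum exceeds the parent) and the rescale factor is logged.
    """
    total = float(sum(children_nested))
    if total <= parent_nested or total == 0.0:
        return [float(c) for c in children_nested]
    factor = parent_nested / total
    logger.info("rescaling %d children by %.6f to fit parent", len(children_nested), factor)
    return [float(c) * factor for c in children_nested]


def track_clones(
    partitions: Mapping[str, ClonePartition] | ClonePartition, tree: CloneTree
) -> PrevalenceTable:
    """Match clones across timepoints by exact signature; nested prevalences.

    ``partitions`` is either one partition per timepoint or a single
    pooled partition carrying per-timepoint counts.  Every observed
    signature must correspond to an observed tree node (run the tree
    construction on the pooled partition); clones absent at a timepoint
    get fraction 0.  Unassigned cells are excluded from denominators.
    """
    if isinstance(partitions, ClonePartition):
        pooled = partitions
        timepoints = list(pooled.timepoint_order)
        counts: dict[str, dict[tuple[int, ...], int]] = {
            tp: {c.signature: c.timepoint_counts.get(tp, 0) for c in pooled.clones}
            for tp in timepoints
        }
        mutation_ids = pooled.mutation_ids
    else:
        timepoints = sorted(
            {tp for p in partitions.values() for tp in p.timepoint_order}
        )
        first = next(iter(partitions.values()))
        mutation_ids = first.mutation_ids
        counts = {}
        for tp, p in partitions.items():
            if p.mutation_ids != mutation_ids:
                raise ValueError("all partitions must share the mutation catalog")
            counts[tp] = {c.signature: c.size for c in p.clones}

    # map signatures to observed tree nodes
    state_code = {"WT": 0, "MUT": 1, "HET": 1, "HOM": 2}
    node_by_sig: dict[tuple[int, ...], CloneNode] = {}
    for n in tree.nodes():
        sig = tuple(state_code[n.signature[mid]] for mid in mutation_ids)
        node_by_sig[sig] = n
    for tp in timepoints:
        for sig in counts[tp]:
            if counts[tp][sig] > 0 and sig not in node_by_sig:
                raise ValueError(
                    f"signature {sig} observed at {tp} is absent from the clone tree"
                )

    rows = []
    nested_cache: dict[tuple[str, int], float] = {}

    def own_fraction(n: CloneNode, tp: str) -> float:
        sig = tuple(state_code[n.signature[mid]] for mid in mutation_ids)
        total = sum(counts[tp].values())
        if total == 0:
            return 0.0
        return counts[tp].get(sig, 0) / total

    def nested(n: CloneNode, tp: str) -> float:
        key = (tp, id(n))
        if key not in nested_cache:
            child_vals = [nested(c, tp) for c in n.children]
            own = own_fraction(n, tp)
            # bottom-up sums keep parent >= child; clamp against float drift
            # and cap at 1 so externally consumed tables always nest
            child_vals = rescale_children(1.0 - own, child_vals) if own + sum(child_vals) > 1.0 else child_vals
            nested_cache[key] = min(own + sum(child_vals), 1.0)
        return nested_cache[key]

    for n in tree.nodes():
        for tp in timepoints:
            rows.append(
                {
                    "clone": n.name,
                    "parent": n.parent.name if n.parent else "",
                    "timepoint": tp,
                    "own_fraction": own_fraction(n, tp),
                    "nested_fraction": nested(n, tp),
                }
            )
    frame = pd.DataFrame(rows)
    return PrevalenceTable(frame=frame, timepoint_order=timepoints)


def frequency_trajectories(m: GenotypeMatrix, order: MutationOrder) -> TrajectoryTable:
    """Mutated fraction per mutation per timepoint plus acquisition rank."""
    rows = []
    for mid in m.mutation_ids:
        row: dict[str, object] = {"mutation": mid, "rank": order.rank(mid)}
        for tp in m.timepoint_order:
            j = m.mutation_index(mid)
            col = m.calls[m.timepoint_mask(tp), j]
            defined = col >= 0
            row[tp] = float((col[defined] >= 1).sum() / defined.sum()) if defined.any() else 0.0
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    return TrajectoryTable(frame=frame, timepoint_order=list(m.timepoint_order))


def zygosity_evolution(m: GenotypeMatrix, mutation_id: str) -> list[FrequencyRecord]:
    """One zygosity distribution per timepoint, in timepoint order."""
    return [zygosity_distribution(m, mutation_id, tp) for tp in m.timepoint_order]


def timescape_records(table: PrevalenceTable, tree: CloneTree) -> list[dict]:
    """JSON-ready records following the timescape/fishplot input convention."""
    parents = {n.name: (n.parent.name if n.parent else None) for n in tree.nodes()}
    records = []
    for _, row in table.frame.iterrows():
        records.append(
            {
                "clone_id": row["clone"],
                "parent": parents.get(row["clone"]),
                "timepoint": row["timepoint"],
                "clonal_prev": round(float(row["nested_fraction"]), 10),
                "own_prev": round(float(row["own_fraction"]), 10),
            }
        )
    return records
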