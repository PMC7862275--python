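"""Read, validate, encode and write single-cell genotype matrices.

The universal substrate of the package is a cells x mutations table of
per-cell genotype calls for a small somatic-mutation panel, with one
timepoint label per cell.  Calls use the four-state alphabet

    WT   wild-type            (VAF code 0)
    HET  heterozygous mutant  (VAF code 0.5)
    HOM  homozygous mutant    (VAF code 1)
    MISSING  no call          (VAF code undefined)

where the numeric codes mirror the per-cell "VAF" convention used when
genotyping single whole-genome-amplified cells by Sanger sequencing: a
cell is scored 0 / 0.5 / 1 for each panel variant.

On-disk format is delimited text (TSV by default): first column cell id,
second column timepoint label, one further column per mutation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeState",
    "Mutation",
    "GenotypeMatrix",
    "ColonyTable",
    "GenotypeFileError",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_mutation_catalog",
    "write_mutation_catalog",
    "read_colony_table",
    "write_colony_table",
    "encode_vaf_matrix",
    "presence_matrix",
    "genotype_counts",
]


class GenotypeState(IntEnum):
    """Per-cell genotype call for one mutation."""

    MISSING = -1
    WT = 0
    HET = 1
    HOM = 2

    @property
    def vaf(self) -> float:
        """Numeric VAF code: 0 / 0.5 / 1, NaN for MISSING."""
        if self is GenotypeState.MISSING:
            return math.nan
        return {GenotypeState.WT: 0.0, GenotypeState.HET: 0.5, GenotypeState.HOM: 1.0}[self]

    @property
    def present(self) -> int:
        """Presence/absence projection: HET and HOM collapse to 1."""
        if self is GenotypeState.MISSING:
            return -1
        return 0 if self is GenotypeState.WT else 1


# accepted input tokens (case-insensitive) -> state
_TOKEN_MAP: dict[str, GenotypeState] = {
    "wt": GenotypeState.WT,
    "0": GenotypeState.WT,
    "0.0": GenotypeState.WT,
    "het": GenotypeState.HET,
    "0.5": GenotypeState.HET,
    "hom": GenotypeState.HOM,
    "1": GenotypeState.HOM,
    "1.0": GenotypeState.HOM,
    "na": GenotypeState.MISSING,
    ".": GenotypeState.MISSING,
    "missing": GenotypeState.MISSING,
    "": GenotypeState.MISSING,
}

# canonical output tokens
_STATE_TOKEN = {
    GenotypeState.WT: "WT",
    GenotypeState.HET: "HET",
    GenotypeState.HOM: "HOM",
    GenotypeState.MISSING: "NA",
}


class GenotypeFileError(ValueError):
    """Malformed genotype / catalog / colony file."""


def parse_token(token: str, *, permissive: bool = False) -> GenotypeState:
    """Map a text token to a :class:`GenotypeState`.

    Unknown tokens raise in strict mode and become MISSING when
    ``permissive`` is set.
    """
    state = _TOKEN_MAP.get(str(token).strip().lower())
    if state is None:
        if permissive:
            return GenotypeState.MISSING
        raise GenotypeFileError(f"unknown genotype token {token!r}")
    return state


@dataclass(frozen=True)
class Mutation:
    """One panel variant.

    ``id`` is the short working name used as a column header (e.g.
    ``TET2a``); the remaining fields carry catalog annotation.
    """

    id: str
    gene: str = ""
    transcript: str = ""
    variant: str = ""
    protein_change: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("mutation id must be non-empty")


@dataclass
class GenotypeMatrix:
    """Cells x mutations call table with per-cell timepoint labels.

    ``calls`` holds :class:`GenotypeState` values as an int8 array of
    shape ``(n_cells, n_mutations)``.  Timepoints are free strings; their
    order is ``timepoint_order`` (user-supplied, default lexicographic).
    """

    cells: list[str]
    timepoints: list[str]
    mutations: list[Mutation]
    calls: np.ndarray
    timepoint_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.cells) != len(set(self.cells)):
            dup = sorted({c for c in self.cells if self.cells.count(c) > 1})
            raise GenotypeFileError(f"duplicate cell id(s): {dup[:5]}")
        if len(self.timepoints) != len(self.cells):
            raise GenotypeFileError("every cell needs a timepoint label")
        if self.calls.shape != (len(self.cells), len(self.mutations)):
            raise GenotypeFileError(
                f"call table shape {self.calls.shape} does not match "
                f"{len(self.cells)} cells x {len(self.mutations)} mutations"
            )
        ids = [m.id for m in self.mutations]
        if len(ids) != len(set(ids)):
            raise GenotypeFileError("duplicate mutation ids in catalog")
        if self.n_cells and not (self.calls >= GenotypeState.MISSING).all() & (
            self.calls <= GenotypeState.HOM
        ).all():
            raise GenotypeFileError("call codes must be in {-1, 0, 1, 2}")
        if not self.timepoint_order:
            self.timepoint_order = sorted(set(self.timepoints))
        else:
            missing = set(self.timepoints) - set(self.timepoint_order)
            if missing:
                raise GenotypeFileError(f"timepoints without an ordering entry: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def mutation_ids(self) -> list[str]:
        return [m.id for m in self.mutations]

    def mutation_index(self, mutation_id: str) -> int:
        try:
            return self.mutation_ids.index(mutation_id)
        except ValueError:
            raise KeyError(f"mutation {mutation_id!r} not in catalog") from None

    def timepoint_mask(self, timepoint: str) -> np.ndarray:
        if timepoint not in self.timepoint_order:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return np.array([t == timepoint for t in self.timepoints], dtype=bool)

    def subset(self, mask: np.ndarray | Sequence[bool]) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            cells=[c for c, keep in zip(self.cells, mask) if keep],
            timepoints=[t for t, keep in zip(self.timepoints, mask) if keep],
            mutations=list(self.mutations),
            calls=self.calls[mask].copy(),
            timepoint_order=list(self.timepoint_order),
        )

    def restrict_timepoint(self, timepoint: str) -> "GenotypeMatrix":
        return self.subset(self.timepoint_mask(timepoint))

    def presence(self) -> np.ndarray:
        """Presence/absence projection (int8; -1 where MISSING)."""
        out = np.where(self.calls >= GenotypeState.HET, 1, 0).astype(np.int8)
        out[self.calls == GenotypeState.MISSING] = -1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Token DataFrame indexed by cell id, with a ``timepoint`` column."""
        tokens = np.vectorize(lambda v: _STATE_TOKEN[GenotypeState(int(v))])(self.calls) if self.n_cells else np.empty((0, self.n_mutations), dtype=object)
        df = pd.DataFrame(tokens, index=pd.Index(self.cells, name="cell_id"), columns=self.mutation_ids)
        df.insert(0, "timepoint", self.timepoints)
        return df

    def copy(self) -> "GenotypeMatrix":
        return self.subset(np.ones(self.n_cells, dtype=bool))


@dataclass
class ColonyTable:
    """Genotype calls for single-cell-derived colonies, one mutation.

    Colonies are genotyped without whole-genome amplification, so calls
    are restricted to the defined states {WT, HET, HOM}.
    """

    colony_ids: list[str]
    mutation_id: str
    calls: np.ndarray
    timepoints: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.colony_ids) != len(set(self.colony_ids)):
            raise GenotypeFileError("duplicate colony id")
        if len(self.timepoints) != len(self.colony_ids) or len(self.calls) != len(self.colony_ids):
            raise GenotypeFileError("colony table columns must have equal length")
        if self.calls.size and ((self.calls < GenotypeState.WT) | (self.calls > GenotypeState.HOM)).any():
            raise GenotypeFileError("colony calls must be WT, HET or HOM (no missing)")

    @property
    def n_colonies(self) -> int:
        return len(self.colony_ids)

    def counts(self, timepoint: str | None = None) -> np.ndarray:
        """(WT, HET, HOM) counts, optionally for one timepoint."""
        calls = self.calls
        if timepoint is not None:
            sel = np.array([t == timepoint for t in self.timepoints], dtype=bool)
            calls = calls[sel]
        return np.bincount(calls, minlength=3)[:3]


# -- genotype matrix IO --------------------------------------------------

def read_genotype_matrix(
    path: str | Path,
    *,
    delimiter: str = "\t",
    permissive: bool = False,
    timepoint_order: Sequence[str] | None = None,
    catalog: Sequence[Mutation] | None = None,
) -> GenotypeMatrix:
    """Read a delimited genotype matrix.

    Layout: header row naming the mutations; first column cell id,
    second column timepoint label.  Tokens are case-insensitive
    (WT/0, HET/0.5, HOM/1, NA/./MISSING).  Unknown tokens raise unless
    ``permissive`` is set, in which case they become MISSING.  Cells
    whose calls are all MISSING are dropped with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GenotypeFileError(f"empty genotype file: {path}") from None
    if df.shape[1] < 3:
        raise GenotypeFileError(
            f"malformed header in {path}: need cell id, timepoint and >=1 mutation column"
        )
    mut_ids = list(df.columns[2:])
    if len(mut_ids) != len(set(mut_ids)):
        raise GenotypeFileError(f"malformed header in {path}: duplicate mutation columns")
    if catalog is not None:
        by_id = {m.id: m for m in catalog}
        unknown = [m for m in mut_ids if m not in by_id]
        if unknown:
            raise GenotypeFileError(f"mutations absent from catalog: {unknown}")
        mutations = [by_id[m] for m in mut_ids]
    else:
        mutations = [Mutation(id=m) for m in mut_ids]

    cells = df.iloc[:, 0].tolist()
    timepoints = df.iloc[:, 1].tolist()
    calls = np.empty((len(cells), len(mut_ids)), dtype=np.int8)
    for j, mut in enumerate(mut_ids):
        for i, token in enumerate(df[mut].tolist()):
            try:
                calls[i, j] = parse_token(token, permissive=permissive)
            except GenotypeFileError:
                raise GenotypeFileError(
                    f"unknown genotype token {token!r} for cell {cells[i]!r}, mutation {mut!r}"
                ) from None

    all_missing = (calls == GenotypeState.MISSING).all(axis=1)
    if all_missing.any():
        dropped = [c for c, d in zip(cells, all_missing) if d]
        logger.warning("dropping %d cell(s) with no defined call: %s", len(dropped), dropped[:5])
        keep = ~all_missing
        cells = [c for c, k in zip(cells, keep) if k]
        timepoints = [t for t, k in zip(timepoints, keep) if k]
        calls = calls[keep]

    return GenotypeMatrix(
        cells=cells,
        timepoints=timepoints,
        mutations=mutations,
        calls=calls,
        timepoint_order=list(timepoint_order) if timepoint_order else [],
    )


def write_genotype_matrix(m: GenotypeMatrix, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write the canonical form: tokens WT/HET/HOM/NA, cell id first."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(["cell_id", "timepoint", *m.mutation_ids]) + "\n")
        for i, (cell, tp) in enumerate(zip(m.cells, m.timepoints)):
            row = [_STATE_TOKEN[GenotypeState(int(v))] for v in m.calls[i]]
            fh.write(delimiter.join([cell, tp, *row]) + "\n")


# -- mutation catalog IO -------------------------------------------------

_CATALOG_COLS = ["id", "gene", "transcript", "variant", "protein_change"]


def read_mutation_catalog(path: str | Path, *, delimiter: str = "\t") -> list[Mutation]:
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GenotypeFileError(f"empty catalog file: {path}") from None
    if "id" not in df.columns:
        raise GenotypeFileError(f"catalog {path} lacks an 'id' column")
    muts = []
    for _, row in df.iterrows():
        muts.append(Mutation(**{c: row.get(c, "") for c in _CATALOG_COLS if c in df.columns}))
    ids = [m.id for m in muts]
    if len(ids) != len(set(ids)):
        raise GenotypeFileError("duplicate mutation id in catalog")
    return muts


def write_mutation_catalog(catalog: Iterable[Mutation], path: str | Path, *, delimiter: str = "\t") -> None:
    rows = [[getattr(m, c) for c in _CATALOG_COLS] for m in catalog]
    pd.DataFrame(rows, columns=_CATALOG_COLS).to_csv(path, sep=delimiter, index=False)


# -- colony table IO -----------------------------------------------------

def read_colony_table(path: str | Path, mutation_id: str, *, delimiter: str = "\t") -> ColonyTable:
    """Read a colony genotype table (columns: colony_id, timepoint, call)."""
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GenotypeFileError(f"empty colony file: {path}") from None
    needed = {"colony_id", "timepoint", "call"}
    if not needed.issubset(df.columns):
        raise GenotypeFileError(f"colony table {path} needs columns {sorted(needed)}")
    calls = np.array([parse_token(t) for t in df["call"]], dtype=np.int8)
    if (calls == GenotypeState.MISSING).any():
        raise GenotypeFileError("colony calls may not be MISSING")
    return ColonyTable(
        colony_ids=df["colony_id"].tolist(),
        mutation_id=mutation_id,
        calls=calls,
        timepoints=df["timepoint"].tolist(),
    )


def write_colony_table(t: ColonyTable, path: str | Path, *, delimiter: str = "\t") -> None:
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(["colony_id", "timepoint", "call"]) + "\n")
        for cid, tp, call in zip(t.colony_ids, t.timepoints, t.calls):
            fh.write(delimiter.join([cid, tp, _STATE_TOKEN[GenotypeState(int(call))]]) + "\n")


# -- numeric encodings ---------------------------------------------------

def encode_vaf_matrix(m: GenotypeMatrix) -> pd.DataFrame:
    """Numeric cell x mutation table: WT->0, HET->0.5, HOM->1, MISSING->NaN."""
    vals = m.calls.astype(float) / 2.0
    vals[m.calls == GenotypeState.MISSING] = np.nan
    return pd.DataFrame(vals, index=pd.Index(m.cells, name="cell_id"), columns=m.mutation_ids)


def presence_matrix(m: GenotypeMatrix) -> pd.DataFrame:
    """Presence/absence projection: {HET, HOM}->1, WT->0, MISSING->NaN."""
    vals = (m.calls >= GenotypeState.HET).astype(float)
    vals[m.calls == GenotypeState.MISSING] = np.nan
    return pd.DataFrame(vals, index=pd.Index(m.cells, name="cell_id"), columns=m.mutation_ids)


def genotype_counts(
    m: GenotypeMatrix, mutation_id: str, timepoint: str | None = None
) -> Mapping[GenotypeState, int]:
    """Counts of each call state for one mutation (optionally one timepoint)."""
    j = m.mutation_index(mutation_id)
    col = m.calls[:, j]
    if timepoint is not None:
        col = col[m.timepoint_mask(timepoint)]
    return {s: int((col == s).sum()) for s in GenotypeState}
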