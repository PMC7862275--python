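"""Synthetic single-cell genotyping datasets with known clonal truth.

The generator emulates the design of a three-timepoint single-cell
Sanger-genotyping study of a myelofibrosis patient progressing to AML:
300 whole-genome-amplified CD34+ cells per timepoint genotyped for a
7-mutation panel (TET2a, JAK2, TET2b, ASXL1, SRSF2, TP53, FLT3), plus
single-cell-derived colonies genotyped for one mutation without WGA.

Ground truth is a rooted clone tree whose edges are single events
(mutation gain WT->HET or zygosity escalation HET->HOM) and a per-clone,
per-timepoint prevalence table.  Observations corrupt the true clone
signature with, in order:

1. per-allele dropout (ADO): each of the two alleles drops independently
   with probability ``d``; a heterozygote with one dropped allele reads
   as WT or HOM, any call with both alleles dropped reads as MISSING;
2. genotype miscalls: with probability ``e`` a defined call is replaced
   by one of the other two defined states, uniformly;
3. extra missingness: with the stated probability the call is overridden
   to MISSING (on top of ADO's both-allele-drop events).

Colonies are genotyped without amplification, so they carry the true
clone signature; clone sampling may be re-weighted by a per-clone
fitness to emulate biased outgrowth in semisolid culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import ColonyTable, GenotypeMatrix, GenotypeState, Mutation

__all__ = [
    "SimClone",
    "SimulationConfig",
    "SimulatedDataset",
    "default_panel",
    "default_config",
    "simulate_cells",
    "simulate_colonies",
    "simulate_dataset",
]

_STATE_OF = {"WT": GenotypeState.WT, "HET": GenotypeState.HET, "HOM": GenotypeState.HOM}
_NAME_OF = {v: k for k, v in _STATE_OF.items()}


@dataclass
class SimClone:
    """One true clone: a full zygosity signature plus its trajectory.

    ``signature`` maps mutation id -> "WT"/"HET"/"HOM"; ``prevalence``
    maps timepoint -> proportion of cells.  ``colony_fitness`` is a
    positive weight multiplying the prevalence when colonies are drawn.
    """

    id: str
    signature: dict[str, str]
    parent: str | None
    prevalence: dict[str, float]
    colony_fitness: float = 1.0

    def signature_codes(self, mutation_ids: Sequence[str]) -> np.ndarray:
        return np.array([_STATE_OF[self.signature.get(m, "WT")] for m in mutation_ids], dtype=np.int8)


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic dataset."""

    clones: list[SimClone]
    mutations: list[Mutation]
    n_cells: dict[str, int]
    ado_rate: float = 0.1
    miscall_rate: float = 0.01
    missing_rate: float = 0.01
    n_colonies: int = 50
    colony_mutation: str = ""
    seed: int = 0
    timepoint_order: list[str] = field(default_factory=list)
    emulated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timepoint_order:
            self.timepoint_order = sorted(self.n_cells)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not 0.0 <= self.ado_rate <= 0.5:
            raise ValueError("ado_rate must be in [0, 0.5]")
        if not 0.0 <= self.miscall_rate <= 0.2:
            raise ValueError("miscall_rate must be in [0, 0.2]")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        ids = [c.id for c in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate clone id")
        by_id = {c.id: c for c in self.clones}
        roots = [c for c in self.clones if c.parent is None]
        if len(roots) != 1:
            raise ValueError(f"clone tree must have exactly one root, found {len(roots)}")
        # connectivity + single-event edges
        mut_ids = [m.id for m in self.mutations]
        for c in self.clones:
            if c.parent is None:
                continue
            if c.parent not in by_id:
                raise ValueError(f"clone {c.id} has unknown parent {c.parent}")
            p = by_id[c.parent]
            diffs = [
                (m, _STATE_OF[p.signature.get(m, "WT")], _STATE_OF[c.signature.get(m, "WT")])
                for m in mut_ids
                if p.signature.get(m, "WT") != c.signature.get(m, "WT")
            ]
            if len(diffs) != 1 or diffs[0][2] - diffs[0][1] != 1:
                raise ValueError(
                    f"clone {c.id} must differ from parent {c.parent} by exactly one "
                    f"gain (WT->HET) or escalation (HET->HOM); got {diffs}"
                )
        # reachability from root
        seen = set()
        stack = [roots[0].id]
        children: dict[str, list[str]] = {}
        for c in self.clones:
            if c.parent is not None:
                children.setdefault(c.parent, []).append(c.id)
        while stack:
            cid = stack.pop()
            seen.add(cid)
            stack.extend(children.get(cid, []))
        if seen != set(ids):
            raise ValueError("clone tree is not connected")
        for tp in self.timepoint_order:
            total = sum(c.prevalence.get(tp, 0.0) for c in self.clones)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"clone prevalences at {tp} sum to {total}, expected 1")

    # -- helpers ---------------------------------------------------------
    @property
    def mutation_ids(self) -> list[str]:
        return [m.id for m in self.mutations]

    def clone_by_id(self, cid: str) -> SimClone:
        return next(c for c in self.clones if c.id == cid)

    def prevalence_vector(self, timepoint: str) -> np.ndarray:
        return np.array([c.prevalence.get(timepoint, 0.0) for c in self.clones])

    def expected_mutated_fraction(self, mutation_id: str, timepoint: str) -> float:
        """Expected fraction of mutated (HET or HOM) cells under the config."""
        return float(
            sum(
                c.prevalence.get(timepoint, 0.0)
                for c in self.clones
                if _STATE_OF[c.signature.get(mutation_id, "WT")] >= GenotypeState.HET
            )
        )

    def expected_nested_prevalence(self, clone_id: str, timepoint: str) -> float:
        """Clone's own prevalence plus all of its descendants'."""
        children: dict[str, list[str]] = {}
        for c in self.clones:
            if c.parent is not None:
                children.setdefault(c.parent, []).append(c.id)
        total = 0.0
        stack = [clone_id]
        while stack:
            cid = stack.pop()
            total += self.clone_by_id(cid).prevalence.get(timepoint, 0.0)
            stack.extend(children.get(cid, []))
        return total

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["clones"] = [SimClone(**c) for c in d["clones"]]
        d["mutations"] = [Mutation(**m) for m in d["mutations"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    """Observed matrix plus the generating truth."""

    config: SimulationConfig
    truth: pd.DataFrame  # cell_id, timepoint, clone_id
    truth_calls: np.ndarray  # true genotype codes, cells x mutations
    observed: GenotypeMatrix
    colonies: ColonyTable | None = None
    colony_clones: pd.DataFrame | None = None  # colony_id, timepoint, clone_id

    def truth_matrix(self) -> GenotypeMatrix:
        """The noise-free genotype matrix implied by the truth labels."""
        return GenotypeMatrix(
            cells=list(self.observed.cells),
            timepoints=list(self.observed.timepoints),
            mutations=list(self.observed.mutations),
            calls=self.truth_calls.copy(),
            timepoint_order=list(self.observed.timepoint_order),
        )


# -- the emulated study design -------------------------------------------

def default_panel() -> list[Mutation]:
    """The 7-variant myeloid panel of the emulated case (catalog rows)."""
    return [
        Mutation("TET2a", "TET2", "NM_001127208", "c.3743T>C", "p.Leu1248Pro"),
        Mutation("JAK2", "JAK2", "NM_004972", "c.1849G>T", "p.Val617Phe"),
        Mutation("TET2b", "TET2", "NM_017628", "c.3409_3416delGGTAATGT", "p.Gly1137Profs*5"),
        Mutation("ASXL1", "ASXL1", "NM_015338", "c.1934dupG", "p.Gly646Trpfs*12"),
        Mutation("SRSF2", "SRSF2", "NM_003016", "c.284C>A", "p.Pro95His"),
        Mutation("TP53", "TP53", "NM_000546", "c.713G>C", "p.Cys238Ser"),
        Mutation("FLT3", "FLT3", "NM_004119", "c.2503G>C", "p.Asp835Tyr"),
    ]


# Nested (clone + descendants) prevalences that pin the printed
# mutated-cell percentages: TP53 20.8%/63%/(decline), FLT3
# 16.6%/25%/35.6%, fully-mutated clone 9%/15%/23%, FLT3-homozygous cells
# present only at the leukemic timepoint.  Values for clones A-E and the
# T3 TP53 fraction are not printed and are emulated (chosen to respect
# fishplot nesting, the halving of the bulk TP53 VAF at T3, and rising
# clonal heterogeneity); they are listed in ``config.emulated``.
_NESTED = {
    #        T1     T2     T3
    "A": (1.000, 1.000, 1.000),
    "B": (0.970, 0.960, 0.970),
    "C": (0.930, 0.900, 0.930),
    "D": (0.880, 0.850, 0.880),
    "E": (0.750, 0.800, 0.700),
    "F": (0.208, 0.630, 0.400),
    "G": (0.166, 0.250, 0.356),
    "I": (0.090, 0.150, 0.230),
    "H": (0.000, 0.000, 0.100),
}

# chain of events: gains in acquisition order, then zygosity escalations
_EVENTS = {
    "A": (None, ("TET2a", "HET")),
    "B": ("A", ("JAK2", "HET")),
    "C": ("B", ("TET2b", "HET")),
    "D": ("C", ("ASXL1", "HET")),
    "E": ("D", ("SRSF2", "HET")),
    "F": ("E", ("TP53", "HET")),
    "G": ("F", ("FLT3", "HET")),
    "I": ("G", ("TP53", "HOM")),
    "H": ("I", ("FLT3", "HOM")),
}

_CHILD_OF = {"A": "B", "B": "C", "C": "D", "D": "E", "E": "F", "F": "G", "G": "I", "I": "H", "H": None}


def default_config(
    *,
    n_cells_per_timepoint: int = 300,
    ado_rate: float = 0.1,
    miscall_rate: float = 0.01,
    missing_rate: float = 0.01,
    n_colonies: int = 50,
    seed: int = 0,
) -> SimulationConfig:
    """Nine-clone, 7-mutation, 3-timepoint configuration of the emulated case.

    Clone prevalences reproduce, in expectation, the printed mutated-cell
    frequencies (TP53 rising 20.8% -> 63% then declining; FLT3 rising
    16.6% -> 25% -> 35.6%) and the fully-mutated clone trajectory
    (9% -> 15% -> 23%); FLT3-homozygous cells appear only at T3.
    """
    tps = ["T1", "T2", "T3"]
    # materialize signatures along the event chain
    signatures: dict[str, dict[str, str]] = {}
    sig: dict[str, str] = {}
    for cid, (parent, (mut, state)) in _EVENTS.items():
        sig = dict(signatures[parent]) if parent else {}
        sig[mut] = state
        signatures[cid] = sig
    clones = []
    for cid, (parent, _) in _EVENTS.items():
        nested = dict(zip(tps, _NESTED[cid]))
        child = _CHILD_OF[cid]
        own = {
            tp: nested[tp] - (dict(zip(tps, _NESTED[child]))[tp] if child else 0.0) for tp in tps
        }
        clones.append(
            SimClone(id=cid, signature=dict(signatures[cid]), parent=parent, prevalence=own)
        )
    return SimulationConfig(
        clones=clones,
        mutations=default_panel(),
        n_cells={tp: n_cells_per_timepoint for tp in tps},
        ado_rate=ado_rate,
        miscall_rate=miscall_rate,
        missing_rate=missing_rate,
        n_colonies=n_colonies,
        colony_mutation="SRSF2",
        seed=seed,
        timepoint_order=tps,
        emulated=[
            "prevalences of clones A-E",
            "TP53 mutated fraction at T3",
            "chain topology of the 9-clone tree",
        ],
    )


# -- forward model --------------------------------------------------------

def _observe(true_calls: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply per-allele ADO, then miscalls, then extra missingness."""
    d, e, miss = cfg.ado_rate, cfg.miscall_rate, cfg.missing_rate
    obs = true_calls.copy()
    # per-allele dropout: two independent allele-drop draws per call
    drop1 = rng.random(obs.shape) < d
    drop2 = rng.random(obs.shape) < d
    het = true_calls == GenotypeState.HET
    hom = true_calls == GenotypeState.HOM
    wt = true_calls == GenotypeState.WT
    both = drop1 & drop2
    # heterozygote: allele 1 = reference, allele 2 = variant
    obs[het & drop1 & ~drop2] = GenotypeState.HOM  # reference dropped
    obs[het & drop2 & ~drop1] = GenotypeState.WT  # variant dropped
    obs[(het | hom | wt) & both] = GenotypeState.MISSING
    # miscalls replace a defined observed state with one of the other two
    defined = obs != GenotypeState.MISSING
    miscall = defined & (rng.random(obs.shape) < e)
    shift = rng.integers(1, 3, size=obs.shape)  # +1 or +2 mod 3
    obs[miscall] = (obs[miscall] + shift[miscall]) % 3
    # extra missingness overrides everything
    obs[rng.random(obs.shape) < miss] = GenotypeState.MISSING
    return obs


def simulate_cells(cfg: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Draw cells per timepoint from the clone prevalences and observe them.

    Clone labels are multinomial draws; the true genotype is the clone
    signature; the observation applies miscall(ADO(truth)) then extra
    missingness.  Fully reproducible from the seed (``cfg.seed`` unless
    overridden); each timepoint uses its own derived substream.
    """
    cfg.validate()
    base = cfg.seed if seed is None else seed
    mut_ids = cfg.mutation_ids
    sig_codes = np.stack([c.signature_codes(mut_ids) for c in cfg.clones])
    cells: list[str] = []
    tps: list[str] = []
    clone_ids: list[str] = []
    true_rows = []
    obs_rows = []
    for k, tp in enumerate(cfg.timepoint_order):
        rng = np.random.default_rng(np.random.SeedSequence([int(base), k]))
        n = cfg.n_cells[tp]
        counts = rng.multinomial(n, cfg.prevalence_vector(tp))
        labels = np.repeat(np.arange(len(cfg.clones)), counts)
        true_calls = sig_codes[labels]
        obs_calls = _observe(true_calls, cfg, rng)
        cells.extend(f"{tp}_c{i:04d}" for i in range(n))
        tps.extend([tp] * n)
        clone_ids.extend(cfg.clones[j].id for j in labels)
        true_rows.append(true_calls)
        obs_rows.append(obs_calls)
    truth_calls = np.vstack(true_rows) if true_rows else np.empty((0, len(mut_ids)), dtype=np.int8)
    obs_calls = np.vstack(obs_rows) if obs_rows else np.empty((0, len(mut_ids)), dtype=np.int8)
    # cells rendered entirely missing by noise carry no information; drop
    keep = (obs_calls != GenotypeState.MISSING).any(axis=1)
    observed = GenotypeMatrix(
        cells=[c for c, k2 in zip(cells, keep) if k2],
        timepoints=[t for t, k2 in zip(tps, keep) if k2],
        mutations=list(cfg.mutations),
        calls=obs_calls[keep],
        timepoint_order=list(cfg.timepoint_order),
    )
    truth = pd.DataFrame(
        {
            "cell_id": [c for c, k2 in zip(cells, keep) if k2],
            "timepoint": [t for t, k2 in zip(tps, keep) if k2],
            "clone_id": [c for c, k2 in zip(clone_ids, keep) if k2],
        }
    )
    return SimulatedDataset(
        config=cfg, truth=truth, truth_calls=truth_calls[keep], observed=observed
    )


def simulate_colonies(
    cfg: SimulationConfig,
    timepoint: str,
    mutation_id: str | None = None,
    seed: int | None = None,
) -> tuple[ColonyTable, pd.DataFrame]:
    """Draw colonies from fitness-reweighted clone prevalences.

    Colony genotype is the true clone signature projected onto one
    mutation (no amplification, hence no ADO).  Returns the table and a
    colony -> clone assignment frame.
    """
    if cfg.n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    mutation_id = mutation_id or cfg.colony_mutation or cfg.mutation_ids[0]
    if mutation_id not in cfg.mutation_ids:
        raise KeyError(f"mutation {mutation_id!r} not in config catalog")
    base = cfg.seed if seed is None else seed
    k = cfg.timepoint_order.index(timepoint)
    rng = np.random.default_rng(np.random.SeedSequence([int(base), 1000 + k]))
    weights = cfg.prevalence_vector(timepoint) * np.array([c.colony_fitness for c in cfg.clones])
    total = weights.sum()
    if total <= 0:
        raise ValueError("all colony sampling weights are zero")
    counts = rng.multinomial(cfg.n_colonies, weights / total)
    labels = np.repeat(np.arange(len(cfg.clones)), counts)
    calls = np.array(
        [_STATE_OF[cfg.clones[j].signature.get(mutation_id, "WT")] for j in labels], dtype=np.int8
    )
    ids = [f"{timepoint}_col{i:03d}" for i in range(cfg.n_colonies)]
    table = ColonyTable(
        colony_ids=ids, mutation_id=mutation_id, calls=calls, timepoints=[timepoint] * len(ids)
    )
    assign = pd.DataFrame(
        {
            "colony_id": ids,
            "timepoint": [timepoint] * len(ids),
            "clone_id": [cfg.clones[j].id for j in labels],
        }
    )
    return table, assign


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Cells plus colonies (for ``cfg.colony_mutation``) at every timepoint."""
    ds = simulate_cells(cfg, seed=seed)
    if cfg.n_colonies >= 1 and cfg.colony_mutation:
        tables, assigns = [], []
        for tp in cfg.timepoint_order:
            t, a = simulate_colonies(cfg, tp, cfg.colony_mutation, seed=seed)
            tables.append(t)
            assigns.append(a)
        ds.colonies = ColonyTable(
            colony_ids=[cid for t in tables for cid in t.colony_ids],
            mutation_id=cfg.colony_mutation,
            calls=np.concatenate([t.calls for t in tables]),
            timepoints=[tp for t in tables for tp in t.timepoints],
        )
        ds.colony_clones = pd.concat(assigns, ignore_index=True)
    return ds
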