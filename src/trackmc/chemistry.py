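"""Step-by-step radiolysis chemistry: diffusion and mutual radical reactions.

Radicals take isotropic Brownian steps (Gaussian displacement, variance 2*D*dt
per axis).  A bimolecular reaction with rate k occurs on contact within the
Smoluchowski radius Rc = k/(4 pi N_A D12); reactions missed between step
endpoints are recovered with the Brownian-bridge probability

    P = exp(-(d1 - Rc)(d2 - Rc) / (D12 dt))

where d1/d2 are the pre-/post-step separations.  Pair search is restricted to
radicals closer than twice the largest reaction radius, found either on a
uniform grid (cell edge = 2 max Rc, same/adjacent cells — the method the
simulation is built around) or with a KD-tree; both enumerate exactly the
pairs within the search radius, so results are identical.

Unit conventions: positions in nm, D in m^2/s, times in s, rates in
L mol^-1 s^-1 in files and m^3 mol^-1 s^-1 internally.
"""

from __future__ import annotations

import importlib.resources as _res
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .constants import CONSTANTS

__all__ = [
    "SpeciesParams",
    "ReactionSpec",
    "ReactionTable",
    "StepSchedule",
    "RadicalEnsemble",
    "SpurSourceParams",
    "reaction_radius",
    "diffuse_step",
    "brownian_bridge_probability",
    "pair_reaction_check",
    "candidate_pairs",
    "chem_step",
    "evolve_radicals",
    "synth_radiolysis_source",
]

_M_TO_NM = 1e9


def _default_chemistry_path() -> Path:
    return Path(str(_res.files("trackmc").joinpath("data", "radiolysis_chemistry.yaml")))


# ---------------------------------------------------------------------------
# chemistry definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """A diffusing chemical species; D = 0 is reserved for static targets."""

    name: str
    D_m2_s: float

    def __post_init__(self) -> None:
        if self.D_m2_s < 0:
            raise ValueError(f"diffusion coefficient of {self.name} must be >= 0")


@dataclass(frozen=True)
class ReactionSpec:
    """A bimolecular reaction channel with its derived reaction radius."""

    reactants: tuple[str, str]
    products: tuple[str, ...]
    k_L_mol_s: float
    D12_m2_s: float
    Rc_m: float

    @property
    def Rc_nm(self) -> float:
        return self.Rc_m * _M_TO_NM


def reaction_radius(k_L_mol_s: float, D12_m2_s: float) -> float:
    """Smoluchowski reaction radius Rc = k/(4 pi N_A D12) in metres.

    k is given in the conventional L mol^-1 s^-1 and converted to
    m^3 mol^-1 s^-1 internally.
    """
    if k_L_mol_s < 0:
        raise ValueError("rate constant must be >= 0")
    if k_L_mol_s == 0:
        return 0.0
    if D12_m2_s <= 0:
        raise ValueError("positive rate with non-positive relative diffusion")
    k_si = k_L_mol_s * 1e-3
    return k_si / (4.0 * math.pi * CONSTANTS.avogadro * D12_m2_s)


class ReactionTable:
    """Species set and mutual reaction channels loaded from a config file."""

    def __init__(self, species: Sequence[SpeciesParams],
                 reactions_raw: Sequence[dict]):
        self.species = {s.name: s for s in species}
        self.names = tuple(self.species)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.D = np.array([self.species[n].D_m2_s for n in self.names])

        self.reactions: list[ReactionSpec] = []
        self._by_pair: dict[tuple[int, int], int] = {}
        for r in reactions_raw:
            a, b = r["reactants"]
            for s in (a, b):
                if s not in self.species:
                    raise ValueError(f"reaction references unknown species {s!r}")
            products = tuple(p for p in r["products"] if p != "H2O")
            for p in products:
                if p not in self.species:
                    raise ValueError(f"reaction produces unknown species {p!r}")
            d12 = self.species[a].D_m2_s + self.species[b].D_m2_s
            # identical reactants: the tabulated k follows the -d[A]/dt = 2k[A]^2
            # convention, so the pair-encounter rate (and hence Rc) carries 2k
            k_eff = float(r["k_L_mol_s"]) * (2.0 if a == b else 1.0)
            spec = ReactionSpec(
                reactants=(a, b), products=products, k_L_mol_s=float(r["k_L_mol_s"]),
                D12_m2_s=d12, Rc_m=reaction_radius(k_eff, d12),
            )
            key = tuple(sorted((self.index[a], self.index[b])))
            if key in self._by_pair:
                raise ValueError(f"duplicate reaction for pair {a}+{b}")
            self._by_pair[key] = len(self.reactions)
            self.reactions.append(spec)

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "ReactionTable":
        path = _default_chemistry_path() if path is None else Path(path)
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesParams(name, float(v["D_m2_s"]))
                   for name, v in raw["species"].items()]
        return cls(species, raw["reactions"])

    def reaction_for(self, si: int, sj: int) -> ReactionSpec | None:
        idx = self._by_pair.get(tuple(sorted((si, sj))))
        return None if idx is None else self.reactions[idx]

    @property
    def max_radius_nm(self) -> float:
        return max((r.Rc_nm for r in self.reactions), default=0.0)


# ---------------------------------------------------------------------------
# radical ensemble
# ---------------------------------------------------------------------------

class RadicalEnsemble:
    """Structure-of-arrays container for the diffusing radicals."""

    def __init__(self, table: ReactionTable,
                 positions_nm: np.ndarray, species_idx: np.ndarray,
                 creation_times_s: np.ndarray | None = None):
        self.table = table
        self.positions_nm = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
        self.species_idx = np.asarray(species_idx, dtype=int)
        n = self.positions_nm.shape[0]
        if self.species_idx.shape != (n,):
            raise ValueError("positions/species shape mismatch")
        self.alive = np.ones(n, dtype=bool)
        self.ids = np.arange(n)
        self.creation_times_s = (np.zeros(n) if creation_times_s is None
                                 else np.asarray(creation_times_s, dtype=float))
        self._next_id = n

    @classmethod
    def from_species_names(cls, table: ReactionTable, positions_nm: np.ndarray,
                           names: Sequence[str]) -> "RadicalEnsemble":
        idx = np.array([table.index[n] for n in names], dtype=int)
        return cls(table, positions_nm, idx)

    def counts(self) -> dict[str, int]:
        out = {n: 0 for n in self.table.names}
        for s in self.species_idx[self.alive]:
            out[self.table.names[s]] += 1
        return out

    def add(self, position_nm: np.ndarray, species_idx: int, t: float) -> int:
        new_id = self._next_id
        self._next_id += 1
        self.positions_nm = np.vstack([self.positions_nm, position_nm[None, :]])
        self.species_idx = np.append(self.species_idx, species_idx)
        self.alive = np.append(self.alive, True)
        self.ids = np.append(self.ids, new_id)
        self.creation_times_s = np.append(self.creation_times_s, t)
        return new_id

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def diffuse_step(positions_nm: np.ndarray, D_m2_s: float | np.ndarray, dt_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """New positions after one Brownian step: Gaussian, variance 2*D*dt per axis."""
    if dt_s < 0:
        raise ValueError("time step must be >= 0")
    pos = np.asarray(positions_nm, dtype=float)
    flat = pos.reshape(-1, 3)
    D = np.broadcast_to(np.asarray(D_m2_s, dtype=float), (flat.shape[0],))
    sigma_nm = np.sqrt(2.0 * D * dt_s) * _M_TO_NM
    step = rng.standard_normal(flat.shape) * sigma_nm[:, None]
    return (flat + step).reshape(pos.shape)


def brownian_bridge_probability(d1_nm: float, d2_nm: float, Rc_nm: float,
                                D12_m2_s: float, dt_s: float) -> float:
    """Probability the pair came within Rc during the step, given endpoints.

    1 when either endpoint separation is already within Rc; otherwise the
    standard independent-pairs bridge exp(-(d1-Rc)(d2-Rc)/(D12 dt)).
    """
    if Rc_nm < 0:
        raise ValueError("reaction radius must be >= 0")
    if d1_nm <= Rc_nm or d2_nm <= Rc_nm:
        return 1.0
    if D12_m2_s <= 0 or dt_s <= 0:
        return 0.0
    d1 = (d1_nm - Rc_nm) * 1e-9
    d2 = (d2_nm - Rc_nm) * 1e-9
    return math.exp(-d1 * d2 / (D12_m2_s * dt_s))


def pair_reaction_check(p1_pre_nm, p1_post_nm, p2_pre_nm, p2_post_nm,
                        Rc_nm: float, D12_m2_s: float, dt_s: float,
                        rng: np.random.Generator) -> bool:
    """Did this pair react during the step?  Certain on end-contact, else bridge."""
    d2 = float(np.linalg.norm(np.asarray(p1_post_nm) - np.asarray(p2_post_nm)))
    if d2 <= Rc_nm:
        return True
    d1 = float(np.linalg.norm(np.asarray(p1_pre_nm) - np.asarray(p2_pre_nm)))
    p = brownian_bridge_probability(d1, d2, Rc_nm, D12_m2_s, dt_s)
    return rng.random() < p


# ---------------------------------------------------------------------------
# neighbour search
# ---------------------------------------------------------------------------

def candidate_pairs(positions_nm: np.ndarray, r_search_nm: float,
                    boxsize_nm: float | None = None,
                    backend: str = "grid") -> np.ndarray:
    """Index pairs (i < j) with separation <= r_search, sorted lexicographically.

    backend "grid" hashes positions onto a uniform grid with cell edge
    r_search and compares same/adjacent cells; "kdtree" uses scipy's cKDTree;
    "brute" compares all pairs.  All three return the identical pair set.
    """
    pos = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    if n < 2 or r_search_nm <= 0:
        return np.empty((0, 2), dtype=int)

    def _dist(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        d = pos[i] - pos[j]
        if boxsize_nm is not None:
            d -= boxsize_nm * np.round(d / boxsize_nm)
        return np.linalg.norm(d, axis=1)

    if backend == "brute":
        i, j = np.triu_indices(n, k=1)
        keep = _dist(i, j) <= r_search_nm
        pairs = np.column_stack([i[keep], j[keep]])
    elif backend == "kdtree":
        from scipy.spatial import cKDTree

        if boxsize_nm is not None:
            tree = cKDTree(np.mod(pos, boxsize_nm), boxsize=boxsize_nm)
        else:
            tree = cKDTree(pos)
        raw = tree.query_pairs(r_search_nm, output_type="ndarray")
        if raw.size == 0:
            return np.empty((0, 2), dtype=int)
        i, j = np.minimum(raw[:, 0], raw[:, 1]), np.maximum(raw[:, 0], raw[:, 1])
        keep = _dist(i, j) <= r_search_nm  # tree uses the same metric; re-filter for ties
        pairs = np.column_stack([i[keep], j[keep]])
    elif backend == "grid":
        cells = np.floor(pos / r_search_nm).astype(np.int64)
        if boxsize_nm is not None:
            ncell = max(int(boxsize_nm // r_search_nm), 1)
            cells = np.mod(cells, ncell)
        buckets: dict[tuple[int, int, int], list[int]] = {}
        for idx, c in enumerate(map(tuple, cells)):
            buckets.setdefault(c, []).append(idx)
        # half stencil: self cell + 13 of the 26 neighbours, so each cell pair
        # is visited once
        offsets = []
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    if (ox, oy, oz) > (0, 0, 0) or (ox, oy, oz) == (0, 0, 0):
                        offsets.append((ox, oy, oz))
        cand_i: list[int] = []
        cand_j: list[int] = []
        for cell, members in buckets.items():
            for off in offsets:
                if off == (0, 0, 0):
                    m = len(members)
                    for a in range(m):
                        for b in range(a + 1, m):
                            cand_i.append(members[a]); cand_j.append(members[b])
                    continue
                nb = (cell[0] + off[0], cell[1] + off[1], cell[2] + off[2])
                if boxsize_nm is not None:
                    nb = (nb[0] % ncell, nb[1] % ncell, nb[2] % ncell)
                    if nb == cell:
                        continue
                other = buckets.get(nb)
                if other:
                    for a in members:
                        for b in other:
                            cand_i.append(a); cand_j.append(b)
        if not cand_i:
            return np.empty((0, 2), dtype=int)
        i = np.asarray(cand_i); j = np.asarray(cand_j)
        i, j = np.minimum(i, j), np.maximum(i, j)
        keep = _dist(i, j) <= r_search_nm
        pairs = np.column_stack([i[keep], j[keep]])
        pairs = np.unique(pairs, axis=0)
    else:
        raise ValueError(f"unknown pair-search backend {backend!r}")

    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

@dataclass
class StepSchedule:
    """Ordered (start time, dt) pairs covering (0, t_end].

    The default plan resolves the dense early spur regime finely and coarsens
    geometrically afterwards: dt = dt_fine while t <= t_fine, then
    dt = max(dt_fine, t/10) capped at dt_max.
    """

    t_end_s: float
    dt_fine_s: float = 0.1e-12
    t_fine_s: float = 10e-12
    dt_max_s: float = 10e-9
    steps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_end_s <= 0 or self.dt_fine_s <= 0:
            raise ValueError("schedule requires t_end > 0 and dt_fine > 0")
        if not self.steps:
            t = 0.0
            while t < self.t_end_s - 1e-30:
                if t < self.t_fine_s:
                    dt = self.dt_fine_s
                else:
                    dt = min(max(self.dt_fine_s, t / 10.0), self.dt_max_s)
                dt = min(dt, self.t_end_s - t)
                self.steps.append((t, dt))
                t += dt

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


# ---------------------------------------------------------------------------
# the evolution loop
# ---------------------------------------------------------------------------

def _apply_reaction(ens: RadicalEnsemble, i: int, j: int, spec: ReactionSpec,
                    t: float, midpoint: np.ndarray, events: list) -> list[int]:
    ens.alive[i] = False
    ens.alive[j] = False
    new_idx = []
    for prod in spec.products:
        sp = ens.table.index[prod]
        ens.add(midpoint.copy(), sp, t)
        new_idx.append(len(ens.alive) - 1)
    events.append((t, spec.reactants, (int(ens.ids[i]), int(ens.ids[j])),
                   spec.products))
    return new_idx


def chem_step(ensemble: RadicalEnsemble, t0: float, dt: float,
              rng: np.random.Generator,
              boundary: tuple | None = None,
              backend: str = "grid",
              events: list | None = None) -> None:
    """Advance the mutual-reaction chemistry by one step of length dt.

    (1) contact sweep — nearest-first reaction of pairs already within Rc,
    cascaded so products can react again; (2) Brownian diffusion of all
    survivors; (3) bridge sweep — pairs now within the search radius react
    with certainty on contact or with the Brownian-bridge probability
    otherwise.  Reacted radicals are removed before later checks in the same
    sweep; conflict resolution is nearest-pair-first with radical-id
    tie-breaks, so a run is reproducible for a fixed seed.
    """
    table = ensemble.table
    r_search = 2.0 * table.max_radius_nm
    boxsize = None
    if boundary is not None and boundary[0] == "periodic":
        boxsize = float(boundary[1])
    ev: list = [] if events is None else events
    t1 = t0 + dt

    alive_idx = np.flatnonzero(ensemble.alive)
    if alive_idx.size >= 2 and r_search > 0:
        # --- contact cascade -------------------------------------------
        while True:
            alive_idx = np.flatnonzero(ensemble.alive)
            if alive_idx.size < 2:
                break
            pos = ensemble.positions_nm[alive_idx]
            pairs = candidate_pairs(pos, r_search, boxsize, backend)
            if pairs.size == 0:
                break
            gi = alive_idx[pairs[:, 0]]
            gj = alive_idx[pairs[:, 1]]
            d = _pair_dist(ensemble.positions_nm, gi, gj, boxsize)
            order = np.lexsort((gj, gi, d))
            reacted_any = False
            for k in order:
                i, j = int(gi[k]), int(gj[k])
                if not (ensemble.alive[i] and ensemble.alive[j]):
                    continue
                spec = table.reaction_for(int(ensemble.species_idx[i]),
                                          int(ensemble.species_idx[j]))
                if spec is None or d[k] > spec.Rc_nm:
                    continue
                mid = _midpoint(ensemble.positions_nm[i],
                                ensemble.positions_nm[j], boxsize)
                _apply_reaction(ensemble, i, j, spec, t0, mid, ev)
                reacted_any = True
            if not reacted_any:
                break

    # --- diffusion ------------------------------------------------------
    alive_idx = np.flatnonzero(ensemble.alive)
    pre_positions = ensemble.positions_nm.copy()
    if alive_idx.size:
        D = table.D[ensemble.species_idx[alive_idx]]
        ensemble.positions_nm[alive_idx] = diffuse_step(
            ensemble.positions_nm[alive_idx], D, dt, rng)
        if boxsize is not None:
            ensemble.positions_nm[alive_idx] = np.mod(
                ensemble.positions_nm[alive_idx], boxsize)
        elif boundary is not None and boundary[0] == "absorbing_sphere":
            center, radius = np.asarray(boundary[1], dtype=float), float(boundary[2])
            r = np.linalg.norm(ensemble.positions_nm[alive_idx] - center, axis=1)
            ensemble.alive[alive_idx[r > radius]] = False

    # --- bridge sweep ----------------------------------------------------
    alive_idx = np.flatnonzero(ensemble.alive)
    if alive_idx.size >= 2 and r_search > 0:
        pos = ensemble.positions_nm[alive_idx]
        pairs = candidate_pairs(pos, r_search, boxsize, backend)
        if pairs.size:
            gi = alive_idx[pairs[:, 0]]
            gj = alive_idx[pairs[:, 1]]
            d2 = _pair_dist(ensemble.positions_nm, gi, gj, boxsize)
            order = np.lexsort((gj, gi, d2))
            for k in order:
                i, j = int(gi[k]), int(gj[k])
                if not (ensemble.alive[i] and ensemble.alive[j]):
                    continue
                spec = table.reaction_for(int(ensemble.species_idx[i]),
                                          int(ensemble.species_idx[j]))
                if spec is None:
                    continue
                if d2[k] <= spec.Rc_nm:
                    react = True
                else:
                    d1 = _pair_dist(pre_positions, np.array([i]),
                                    np.array([j]), boxsize)[0]
                    p = brownian_bridge_probability(
                        d1, d2[k], spec.Rc_nm, spec.D12_m2_s, dt)
                    react = rng.random() < p
                if react:
                    mid = _midpoint(ensemble.positions_nm[i],
                                    ensemble.positions_nm[j], boxsize)
                    _apply_reaction(ensemble, i, j, spec, t1, mid, ev)


def evolve_radicals(ensemble: RadicalEnsemble,
                    schedule: StepSchedule,
                    rng: np.random.Generator,
                    boundary: tuple | None = None,
                    backend: str = "grid",
                    record_events: bool = False):
    """Run the chemical stage over the schedule; return the timeline.

    Applies `chem_step` over every (t, dt) of the schedule.

    boundary: None (unbounded), ("periodic", box_nm) or
    ("absorbing_sphere", center_nm, radius_nm).

    Returns (timeline, events) where timeline is a list of
    (t_s, {species: count}) including t = 0, and events is the reaction log
    (populated when record_events is True).
    """
    timeline: list[tuple[float, dict[str, int]]] = [(0.0, ensemble.counts())]
    events: list = []
    for t0, dt in schedule:
        chem_step(ensemble, t0, dt, rng, boundary, backend,
                  events if record_events else None)
        timeline.append((t0 + dt, ensemble.counts()))
    return timeline, events


def _pair_dist(positions: np.ndarray, i: np.ndarray, j: np.ndarray,
               boxsize: float | None) -> np.ndarray:
    d = positions[i] - positions[j]
    if boxsize is not None:
        d -= boxsize * np.round(d / boxsize)
    return np.linalg.norm(d, axis=1)


def _midpoint(a: np.ndarray, b: np.ndarray, boxsize: float | None) -> np.ndarray:
    if boxsize is None:
        return 0.5 * (a + b)
    d = b - a
    d -= boxsize * np.round(d / boxsize)
    return np.mod(a + 0.5 * d, boxsize)


# ---------------------------------------------------------------------------
# synthetic radiolysis source
# ---------------------------------------------------------------------------

@dataclass
class SpurSourceParams:
    """Synthetic spur generator: Gaussian radical clusters along a segment.

    Emulates the spatial structure of the radical distribution at the start of
    the chemical stage (~1 ps): `n_spurs` isotropic Gaussian clusters of RMS
    radius `spur_sigma_nm`, spaced `spur_spacing_nm` apart along `axis` from
    `origin_nm`, with species drawn from `fractions`.  `edep_per_radical_eV`
    sets the nominal physical-stage energy deposit used for G-values.
    """

    n_radicals: int = 400
    n_spurs: int = 10
    spur_spacing_nm: float = 10.0
    spur_sigma_nm: float = 3.0
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fractions: dict[str, float] = field(default_factory=lambda: {
        "OH": 5.5, "e_aq": 4.7, "H3O+": 4.7, "H": 0.6, "H2": 0.15,
    })
    edep_per_radical_eV: float = 6.4

    @property
    def edep_eV(self) -> float:
        return self.n_radicals * self.edep_per_radical_eV


def synth_radiolysis_source(params: SpurSourceParams, table: ReactionTable,
                            rng: np.random.Generator) -> RadicalEnsemble:
    """Generate the initial radical ensemble from the spur parameters."""
    fr = {k: float(v) for k, v in params.fractions.items()}
    total = sum(fr.values())
    if total <= 0 or any(v < 0 for v in fr.values()):
        raise ValueError("species fractions must be non-negative and sum > 0")
    names = list(fr)
    p = np.array([fr[n] / total for n in names])
    for n in names:
        if n not in table.species:
            raise ValueError(f"source species {n!r} not in the reaction table")

    n = params.n_radicals
    spur_of = np.arange(n) % params.n_spurs
    axis = np.asarray(params.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    centers = (np.asarray(params.origin_nm, dtype=float)[None, :]
               + np.outer(spur_of * params.spur_spacing_nm, axis))
    positions = centers + rng.standard_normal((n, 3)) * params.spur_sigma_nm
    species_names = rng.choice(names, size=n, p=p)
    idx = np.array([table.index[s] for s in species_names], dtype=int)
    return RadicalEnsemble(table, positions, idx)
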