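"""Concurrent radical-DNA reactions, damage recording and SSB/DSB scoring.

During the chemical stage the radical-DNA reaction sweep runs every `ti`
(the check interval): each radical queries its two-voxel nearest DNA element
and reacts on contact within R + Rc, via histone scavenging (probability Ps,
no damage recorded), or through the Brownian bridge over the elapsed
sub-interval.  Setting ti >= tc recovers the overlay method (a single sweep
at the end of the chemical stage).

Strand-break scoring converts indirect sugar-phosphate damage sites into
strand breaks with a fixed probability, converts direct energy deposits with
a linear 5 -> 37.5 eV ramp, and pairs breaks on opposite strands within
10 bp into double-strand breaks by a greedy left-to-right walk along the
chain (optimal for this on-a-line pairing problem).
"""

from __future__ import annotations

import importlib.resources as _res
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chemistry import (
    RadicalEnsemble,
    ReactionTable,
    SpurSourceParams,
    StepSchedule,
    brownian_bridge_probability,
    chem_step,
    reaction_radius,
    synth_radiolysis_source,
)
from .dna_geometry import (
    DNAGeometry,
    DNAGeometryParams,
    KIND_BASE,
    KIND_HISTONE,
    KIND_SUGAR,
    generate_nucleus_geometry,
    nearest_dna_element,
    strip_initial_radicals,
)
from .observables import g_value

__all__ = [
    "DNAReactionParams",
    "DamageSite",
    "BreakRules",
    "BreakSummary",
    "dna_reaction_sweep",
    "concurrent_evolve",
    "classify_breaks",
    "SweepConfig",
    "sweep_experiment",
]

#: radicals farther than this from the nearest element surface skip the
#: bridge evaluation entirely (matches the 2-nm neighbour-search trigger)
BRIDGE_WINDOW_NM = 2.0

_M_TO_NM = 1e9


def _default_dna_path() -> Path:
    return Path(str(_res.files("trackmc").joinpath("data", "dna_reactions.yaml")))


class DNAReactionParams:
    """Radical-DNA reaction rates, derived radii and histone scavenging.

    Rates are per species against the (type-averaged) base and the
    sugar-phosphate group; a non-positive rate disables the channel.  The DNA
    is static, so the relative diffusion coefficient of a channel is the
    radical's own D and Rc = k/(4 pi N_A D) — below 1 nm for every channel,
    which the constructor asserts because the two-voxel search relies on it.
    """

    def __init__(self, rates: dict[str, dict[str, float]],
                 scavenge_probability: float,
                 chem_table: ReactionTable,
                 per_base: dict[str, dict[str, float]] | None = None):
        if not (0.0 <= scavenge_probability <= 1.0):
            raise ValueError("scavenging probability must lie in [0, 1]")
        self.scavenge_probability = float(scavenge_probability)
        # YAML 1.1 reads exponent literals without a sign (6.95e9) as strings
        self.per_base = {sp: {b: float(v) for b, v in d.items()}
                         for sp, d in (per_base or {}).items()}
        self.rates = {sp: {t: float(v) for t, v in d.items()}
                      for sp, d in rates.items()}
        rates = self.rates
        self._rc_nm: dict[tuple[str, int], float] = {}
        self._rate: dict[tuple[str, int], float] = {}
        for species, chans in rates.items():
            if species not in chem_table.species:
                raise ValueError(f"unknown radical species {species!r}")
            D = chem_table.species[species].D_m2_s
            for target, kind in (("base", KIND_BASE), ("sugar", KIND_SUGAR)):
                k = float(chans.get(target, -1.0))
                self._rate[(species, kind)] = k
                if k > 0:
                    rc = reaction_radius(k, D) * _M_TO_NM
                    if rc >= 1.0:
                        raise ValueError(
                            f"reaction radius {rc:.3f} nm for {species}-{target} "
                            "breaks the < 1 nm contract of the two-voxel search"
                        )
                    self._rc_nm[(species, kind)] = rc

    @classmethod
    def from_file(cls, chem_table: ReactionTable,
                  path: str | Path | None = None) -> "DNAReactionParams":
        path = _default_dna_path() if path is None else Path(path)
        raw = yaml.safe_load(Path(path).read_text())
        return cls(raw["rates"], float(raw["scavenge_probability"]), chem_table,
                   per_base=raw.get("per_base"))

    def averaged_base_rate(self, species: str) -> float:
        """Mean of the per-base (A, G, C, T) rates for one radical species."""
        vals = self.per_base.get(species)
        if not vals:
            raise ValueError(f"no per-base rates recorded for {species!r}")
        return float(np.mean(list(vals.values())))

    def rate(self, species: str, kind: int) -> float:
        return self._rate.get((species, kind), -1.0)

    def rc_nm(self, species: str, kind: int) -> float:
        return self._rc_nm.get((species, kind), 0.0)

    def max_rc_nm(self) -> float:
        return max(self._rc_nm.values(), default=0.0)


@dataclass(frozen=True)
class DamageSite:
    """One recorded radical or direct hit on a DNA base or sugar group."""

    time_s: float
    bp: int
    strand: int           # -1 for base (spans both strands)
    kind: int             # KIND_BASE | KIND_SUGAR
    source: str           # "indirect-OH", "indirect-e_aq", "direct"


# ---------------------------------------------------------------------------
# the radical-DNA sweep
# ---------------------------------------------------------------------------

def dna_reaction_sweep(ensemble: RadicalEnsemble, geom: DNAGeometry,
                       params: DNAReactionParams,
                       prev_positions_nm: np.ndarray,
                       dt_elapsed_s: float,
                       t_s: float,
                       rng: np.random.Generator) -> tuple[list[DamageSite], list[int]]:
    """One radical-DNA check over all alive radicals, in radical-id order.

    Contact within R + Rc records a damage site (base/sugar) or scavenges
    with probability Ps (histone, no record); otherwise the Brownian bridge
    over the elapsed interval is evaluated against the same nearest element.
    Returns the new damage sites and the ensemble indices removed.
    """
    sites: list[DamageSite] = []
    removed: list[int] = []
    names = ensemble.table.names
    for i in np.flatnonzero(ensemble.alive):
        pos = ensemble.positions_nm[i]
        ne = nearest_dna_element(geom, pos)
        if ne is None:
            continue
        if ne.kind == KIND_HISTONE:
            if ne.surface_distance_nm <= 0.0:
                if rng.random() < params.scavenge_probability:
                    ensemble.alive[i] = False
                    removed.append(int(i))
            continue
        species = names[ensemble.species_idx[i]]
        k = params.rate(species, ne.kind)
        if k <= 0:
            continue
        rc = params.rc_nm(species, ne.kind)
        d2 = ne.surface_distance_nm
        hit = False
        if d2 <= rc:
            hit = True
        elif d2 <= BRIDGE_WINDOW_NM and dt_elapsed_s > 0:
            prev = prev_positions_nm[i]
            v = geom.voxels[ne.voxel]
            d1 = float(np.linalg.norm(v["centers"][ne.index] - prev)
                       - v["radii"][ne.index])
            D = ensemble.table.species[species].D_m2_s
            p = brownian_bridge_probability(d1, d2, rc, D, dt_elapsed_s)
            hit = rng.random() < p
        if hit:
            ensemble.alive[i] = False
            removed.append(int(i))
            sites.append(DamageSite(time_s=t_s, bp=ne.bp, strand=ne.strand,
                                    kind=ne.kind, source=f"indirect-{species}"))
    return sites, removed


def concurrent_evolve(ensemble: RadicalEnsemble, geom: DNAGeometry,
                      schedule: StepSchedule, params: DNAReactionParams,
                      rng: np.random.Generator,
                      ti_s: float,
                      boundary: tuple | None = None,
                      backend: str = "grid"):
    """Chemical stage with radical-DNA checks every `ti` and at the end.

    The caller is expected to have stripped the radicals created inside the
    chromatin (see `dna_geometry.strip_initial_radicals`).  A check runs
    after the first chemistry step whose end time satisfies
    t - t_last_check >= ti, and a final check runs at the end of the stage.
    ti >= tc therefore reproduces the overlay method: pure chemistry followed
    by a single end-of-stage sweep.

    Returns (damage sites, timeline, ensemble).
    """
    if ti_s <= 0:
        raise ValueError("check interval ti must be positive")
    timeline: list[tuple[float, dict[str, int]]] = [(0.0, ensemble.counts())]
    sites: list[DamageSite] = []
    prev_check = ensemble.positions_nm.copy()
    t_last = 0.0
    t1 = 0.0
    for t0, dt in schedule:
        t1 = t0 + dt
        chem_step(ensemble, t0, dt, rng, boundary, backend)
        # products created during the step enter the check with their birth
        # position as the bridge start point
        if ensemble.positions_nm.shape[0] > prev_check.shape[0]:
            extra = ensemble.positions_nm[prev_check.shape[0]:]
            prev_check = np.vstack([prev_check, extra])
        if t1 - t_last >= ti_s:
            new_sites, _ = dna_reaction_sweep(
                ensemble, geom, params, prev_check, t1 - t_last, t1, rng)
            sites.extend(new_sites)
            prev_check = ensemble.positions_nm.copy()
            t_last = t1
        timeline.append((t1, ensemble.counts()))
    if t1 > t_last:
        new_sites, _ = dna_reaction_sweep(
            ensemble, geom, params, prev_check, t1 - t_last, t1, rng)
        sites.extend(new_sites)
    return sites, timeline, ensemble


# ---------------------------------------------------------------------------
# strand-break classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakRules:
    """Conversion of damage sites to strand breaks and break pairing."""

    p_indirect_sugar_break: float = 0.4
    direct_energy_min_eV: float = 5.0
    direct_energy_max_eV: float = 37.5
    dsb_max_bp: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_indirect_sugar_break <= 1.0):
            raise ValueError("break probability must lie in [0, 1]")
        if self.direct_energy_max_eV <= self.direct_energy_min_eV:
            raise ValueError("direct-damage ramp must have max > min")
        if self.dsb_max_bp < 0:
            raise ValueError("DSB pairing distance must be >= 0")

    def direct_break_probability(self, energy_eV: float) -> float:
        lo, hi = self.direct_energy_min_eV, self.direct_energy_max_eV
        return float(np.clip((energy_eV - lo) / (hi - lo), 0.0, 1.0))


@dataclass
class BreakSummary:
    """SSB/DSB counts with per-source breakdown."""

    ssb: int = 0
    dsb: int = 0
    n_breaks: int = 0
    base_damage: int = 0
    by_source: dict[str, int] = field(default_factory=dict)

    def relative_yield(self, reference: "BreakSummary") -> float:
        if reference.dsb <= 0:
            raise ValueError("relative DSB yield undefined for a zero reference")
        return self.dsb / reference.dsb


def greedy_pair_breaks(breaks: Sequence[tuple[int, int]], max_bp: int) -> int:
    """Number of DSBs from greedy left-to-right pairing of (bp, strand) breaks.

    Walk the breaks in increasing bp (ties: lower strand first); pair each
    unpaired break with the nearest unpaired opposite-strand break within
    max_bp ahead of it.
    """
    items = sorted(set(breaks))
    paired = [False] * len(items)
    dsb = 0
    for a in range(len(items)):
        if paired[a]:
            continue
        for b in range(a + 1, len(items)):
            if items[b][0] - items[a][0] > max_bp:
                break
            if not paired[b] and items[b][1] != items[a][1]:
                paired[a] = paired[b] = True
                dsb += 1
                break
    return dsb


def classify_breaks(sites: Sequence[DamageSite],
                    rules: BreakRules,
                    rng: np.random.Generator,
                    direct_hits: Sequence[tuple[int, int, float]] = (),
                    ) -> BreakSummary:
    """Convert damage sites to strand breaks and pair them into DSBs.

    Indirect sugar-phosphate sites break their strand with probability
    `p_indirect_sugar_break`; direct hits (bp, strand, energy_eV) break with
    the linear energy ramp.  Base damage is counted but never contributes a
    break.  Random draws are consumed in site order, so the classification of
    a time-prefix of a site list is itself a prefix-consistent run.
    """
    summary = BreakSummary()
    breaks: list[tuple[int, int]] = []
    for s in sites:
        summary.by_source[s.source] = summary.by_source.get(s.source, 0) + 1
        if s.kind == KIND_BASE:
            summary.base_damage += 1
            continue
        if rng.random() < rules.p_indirect_sugar_break:
            breaks.append((s.bp, s.strand))
    for bp, strand, energy in direct_hits:
        if rng.random() < rules.direct_break_probability(energy):
            breaks.append((bp, strand))

    unique = sorted(set(breaks))
    summary.n_breaks = len(unique)
    summary.dsb = greedy_pair_breaks(unique, rules.dsb_max_bp)
    summary.ssb = summary.n_breaks - 2 * summary.dsb
    return summary


# ---------------------------------------------------------------------------
# reduced-scale sweep experiments
# ---------------------------------------------------------------------------

@dataclass
class SweepConfig:
    """Configuration of the reduced-scale ti/tc/Ps sweep experiments."""

    seed: int = 0
    replicates: int = 20
    ti_s: float = 1e-12
    ti_values_s: tuple[float, ...] = (1e-12, 1e-10, 2.5e-9)
    tc_values_s: tuple[float, ...] = (1e-9, 2.5e-9, 1e-8)
    ps_values: tuple[float, ...] = (0.0, 0.5, 1.0)
    tc_for_ps_s: float = 2.5e-9
    geometry: DNAGeometryParams = field(default_factory=lambda: DNAGeometryParams(
        n_voxels=(3, 3, 3), histone_every_bp=50))
    source: SpurSourceParams = field(default_factory=lambda: SpurSourceParams(
        n_radicals=800, n_spurs=24, spur_spacing_nm=6.0, spur_sigma_nm=5.0,
        origin_nm=(5.0, 27.5, 27.5), axis=(1.0, 0.0, 0.0)))
    rules: BreakRules = field(default_factory=BreakRules)


def _replicate_run(cfg: SweepConfig, geom: DNAGeometry, chem: ReactionTable,
                   params: DNAReactionParams, rep_seed: int,
                   tc: float, ti: float):
    """One concurrent replicate: returns (damage sites, timeline, edep_eV)."""
    rng = np.random.default_rng(rep_seed)
    ens = synth_radiolysis_source(cfg.source, chem, rng)
    keep = strip_initial_radicals(ens.positions_nm, geom)
    ens.alive &= keep
    schedule = StepSchedule(t_end_s=tc)
    sites, timeline, _ = concurrent_evolve(ens, geom, schedule, params, rng, ti)
    return sites, timeline, cfg.source.edep_eV


def sweep_experiment(cfg: SweepConfig,
                     chemistry_path: str | Path | None = None,
                     dna_path: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Run the reduced-scale experiment suite; returns result tables.

    Tables: "g_vs_tc" (OH yield at each chemical-stage duration, ti fixed),
    "dsb_vs_ti" (DSB per replicate vs check interval), "rt_vs_tc" (relative
    DSB yield vs duration, reference tc = 1 ns), "dsb_vs_ps" (DSB vs histone
    scavenging probability, paired seeds).  Each row carries the replicate
    mean and SD.
    """
    chem = ReactionTable.from_file(chemistry_path)
    params_by_ps: dict[float, DNAReactionParams] = {}

    def params_for(ps: float) -> DNAReactionParams:
        if ps not in params_by_ps:
            raw = yaml.safe_load((Path(dna_path) if dna_path else _default_dna_path()
                                  ).read_text())
            params_by_ps[ps] = DNAReactionParams(
                raw["rates"], ps, chem, per_base=raw.get("per_base"))
        return params_by_ps[ps]

    geom = generate_nucleus_geometry(cfg.geometry, seed=cfg.seed)
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.replicates)]
    tc_max = max(cfg.tc_values_s)
    p1 = params_for(1.0)

    # --- single run per replicate to tc_max; threshold sites/counts by tc ---
    g_rows, rt_rows = [], []
    oh_at, dsb_at = {tc: [] for tc in cfg.tc_values_s}, {tc: [] for tc in cfg.tc_values_s}
    for r, seed in enumerate(rep_seeds):
        sites, timeline, edep = _replicate_run(cfg, geom, chem, p1, seed,
                                               tc_max, cfg.ti_s)
        times = np.array([t for t, _ in timeline])
        oh_counts = np.array([c["OH"] for _, c in timeline])
        for tc in cfg.tc_values_s:
            idx = int(np.searchsorted(times, tc * (1 + 1e-12), side="right") - 1)
            oh_at[tc].append(oh_counts[idx])
            prefix = [s for s in sites if s.time_s <= tc * (1 + 1e-12)]
            summary = classify_breaks(prefix, cfg.rules,
                                      np.random.default_rng(seed ^ 0x5EED))
            dsb_at[tc].append(summary.dsb)
    for tc in cfg.tc_values_s:
        g = [g_value(c, cfg.source.edep_eV) for c in oh_at[tc]]
        g_rows.append({"tc_s": tc, "ti_s": cfg.ti_s,
                       "G_OH_mean": float(np.mean(g)), "G_OH_sd": float(np.std(g, ddof=1)),
                       "n": cfg.replicates})
        rt_rows.append({"tc_s": tc, "dsb_mean": float(np.mean(dsb_at[tc])),
                        "dsb_sd": float(np.std(dsb_at[tc], ddof=1)),
                        "n": cfg.replicates})
    ref = rt_rows[[r["tc_s"] for r in rt_rows].index(min(cfg.tc_values_s))]["dsb_mean"]
    for r in rt_rows:
        r["Rt"] = r["dsb_mean"] / ref if ref > 0 else math.nan

    # --- DSB vs ti ---------------------------------------------------------
    ti_rows = []
    for ti in cfg.ti_values_s:
        dsbs = []
        for seed in rep_seeds:
            sites, _, _ = _replicate_run(cfg, geom, chem, p1, seed,
                                         cfg.tc_for_ps_s, ti)
            summary = classify_breaks(sites, cfg.rules,
                                      np.random.default_rng(seed ^ 0x5EED))
            dsbs.append(summary.dsb)
        ti_rows.append({"ti_s": ti, "tc_s": cfg.tc_for_ps_s,
                        "dsb_mean": float(np.mean(dsbs)),
                        "dsb_sd": float(np.std(dsbs, ddof=1)), "n": cfg.replicates})

    # --- DSB vs Ps (paired seeds) -----------------------------------------
    ps_rows = []
    for ps in cfg.ps_values:
        dsbs = []
        for seed in rep_seeds:
            sites, _, _ = _replicate_run(cfg, geom, chem, params_for(ps), seed,
                                         cfg.tc_for_ps_s, cfg.ti_s)
            summary = classify_breaks(sites, cfg.rules,
                                      np.random.default_rng(seed ^ 0x5EED))
            dsbs.append(summary.dsb)
        ps_rows.append({"Ps": ps, "tc_s": cfg.tc_for_ps_s,
                        "dsb_mean": float(np.mean(dsbs)),
                        "dsb_sd": float(np.std(dsbs, ddof=1)), "n": cfg.replicates})

    return {
        "g_vs_tc": pd.DataFrame(g_rows),
        "rt_vs_tc": pd.DataFrame(rt_rows),
        "dsb_vs_ti": pd.DataFrame(ti_rows),
        "dsb_vs_ps": pd.DataFrame(ps_rows),
    }
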