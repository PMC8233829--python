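"""Physics summary statistics: LET, range, radial dose, dose, G-values.

The length-averaged unrestricted LET is the ratio of summed per-collision
energy losses to summed free-flight distances, LET = sum(eps_i)/sum(s_j);
the path-weighted mean of eps_i/s_i reduces to the same ratio identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS, EV_TO_JOULE, PhysicalConstants
from .cross_sections import CrossSectionTable
from .transport import Track, _ChannelSet, sample_free_path, select_channel, \
    sample_ejected_electron, sample_excitation_loss
from .effective_charge import effective_charge

__all__ = [
    "RadialDoseSpec",
    "track_let",
    "let_at_energy",
    "csda_range",
    "radial_dose",
    "dose_in_volume",
    "g_value",
]


def track_let(losses_eV: np.ndarray, lengths_m: np.ndarray) -> float:
    """Length-averaged unrestricted LET (eV/m) from (eps_i, s_i) samples."""
    losses = np.asarray(losses_eV, dtype=float)
    lengths = np.asarray(lengths_m, dtype=float)
    if losses.size == 0 or lengths.size == 0:
        raise ValueError("LET requires at least one (loss, length) sample")
    if np.any(lengths <= 0) or np.any(losses < 0):
        raise ValueError("require s_i > 0 and eps_i >= 0")
    return float(losses.sum() / lengths.sum())


def let_at_energy(Z: int, A: int, Ek_eV: float, table: CrossSectionTable,
                  n_samples: int = 100_000,
                  rng: np.random.Generator | None = None,
                  constants: PhysicalConstants = CONSTANTS) -> float:
    """Monte Carlo LET (eV/m) at a fixed energy from independent collisions.

    Draws `n_samples` single-collision (energy loss, free path) pairs at the
    given kinetic energy — the fixed-energy estimator used for LET curves —
    and returns sum(eps)/sum(s).
    """
    rng = np.random.default_rng() if rng is None else rng
    channels = _ChannelSet(table)
    Ep = Ek_eV / A
    sig = table.lookup(Ep)
    zeff = effective_charge(Z, A, Ek_eV, constants)
    sigma_t = zeff**2 * float(sig.sum())

    losses = np.empty(n_samples)
    lengths = np.empty(n_samples)
    for i in range(n_samples):
        lengths[i] = sample_free_path(sigma_t, rng, constants)
        idx = select_channel(sig, rng)
        kind = channels.kinds[idx]
        payload = channels.payload[idx]
        if kind == "ionization":
            Ee, _, _ = sample_ejected_electron(payload, Ep, rng, constants)
            losses[i] = Ee + payload.binding_eV
        elif kind == "excitation_high":
            losses[i] = sample_excitation_loss(payload, Ep, rng, constants)
        else:
            losses[i] = payload.E_eV
    return track_let(losses, lengths)


def csda_range(tracks: list[Track]) -> tuple[float, float]:
    """Mean and SD (m) of the straight-line start-to-end distance of tracks.

    Escaped tracks are excluded (with a warning) because their endpoint is the
    ROI boundary, not the stopping point.
    """
    import warnings

    ranges = []
    for t in tracks:
        if t.termination != "cutoff":
            warnings.warn("excluding escaped track from range estimate")
            continue
        ranges.append(np.linalg.norm(t.end_nm - t.start_nm) * 1e-9)
    if not ranges:
        raise ValueError("no cutoff-terminated tracks")
    arr = np.asarray(ranges)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass(frozen=True)
class RadialDoseSpec:
    """Analysis window and binning for the radial dose profile around the axis."""

    axis_origin_nm: np.ndarray
    axis_direction: np.ndarray
    window_min_nm: float = 4000.0
    window_max_nm: float = 6000.0
    dr_nm: float = 1.0
    r_max_nm: float = 2000.0

    def __post_init__(self) -> None:
        if self.dr_nm <= 0 or self.window_max_nm <= self.window_min_nm:
            raise ValueError("invalid radial dose specification")


def radial_dose(positions_nm: np.ndarray, energies_eV: np.ndarray,
                spec: RadialDoseSpec,
                constants: PhysicalConstants = CONSTANTS,
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Dose (Gy) vs radius in 1-nm annuli within the axial analysis window.

    Returns (bin inner radii in nm, dose per annulus in Gy, overflow energy
    in eV beyond r_max).  Energy is conserved: binned energy plus overflow
    equals the total deposit energy inside the window.
    """
    pos = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
    e = np.asarray(energies_eV, dtype=float)
    d = np.asarray(spec.axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = pos - np.asarray(spec.axis_origin_nm, dtype=float)
    axial = rel @ d
    radial = np.linalg.norm(rel - np.outer(axial, d), axis=1)

    in_window = (axial >= spec.window_min_nm) & (axial <= spec.window_max_nm)
    r = radial[in_window]
    ew = e[in_window]

    nbins = int(math.ceil(spec.r_max_nm / spec.dr_nm))
    edges = np.arange(nbins + 1) * spec.dr_nm
    energy_bins, _ = np.histogram(r, bins=edges, weights=ew)
    overflow = float(ew[r >= edges[-1]].sum())

    # annulus masses: pi (r2^2 - r1^2) * slab thickness * density
    thickness_m = (spec.window_max_nm - spec.window_min_nm) * 1e-9
    r1 = edges[:-1] * 1e-9
    r2 = edges[1:] * 1e-9
    masses = math.pi * (r2**2 - r1**2) * thickness_m * constants.water_density_kg_m3
    dose = energy_bins * EV_TO_JOULE / masses
    return edges[:-1], dose, overflow


def dose_in_volume(positions_nm: np.ndarray, energies_eV: np.ndarray,
                   center_nm: np.ndarray, radius_nm: float,
                   constants: PhysicalConstants = CONSTANTS) -> float:
    """Dose (Gy) to a water sphere from the deposits inside it."""
    if radius_nm <= 0:
        raise ValueError("volume radius must be positive")
    pos = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
    e = np.asarray(energies_eV, dtype=float)
    if pos.shape[0] == 0:
        return 0.0
    inside = np.linalg.norm(pos - np.asarray(center_nm, dtype=float), axis=1) <= radius_nm
    mass = (4.0 / 3.0) * math.pi * (radius_nm * 1e-9) ** 3 * constants.water_density_kg_m3
    return float(e[inside].sum()) * EV_TO_JOULE / mass


def g_value(count: float, edep_eV: float) -> float:
    """Chemical yield G: species per 100 eV of deposited energy."""
    if edep_eV <= 0:
        raise ValueError("deposited energy must be positive")
    return 100.0 * count / edep_eV
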