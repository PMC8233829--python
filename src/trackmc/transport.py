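"""Physical-stage Monte Carlo engine for protons and heavy ions in water.

Event-by-event transport: exponential free flight from the total cross-section,
channel selection proportional to the per-channel cross-sections, closed-form
inversion + rejection sampling of the ejected-electron energy (ionization) and
of the energy loss (excitation).  The primary is never deflected; secondary
electrons are not transported but written to a phase-space stack for an
external electron engine.

Unit conventions: particle positions are in nm, path lengths in m, energies
in eV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .cross_sections import (
    CrossSectionTable,
    ExcitationChannelHigh,
    ExcitationChannelLow,
    KinematicContext,
    ShellParams,
    load_excitation_high,
    load_excitation_low,
    shell_params,
)
from .effective_charge import effective_charge

__all__ = [
    "ParticleState",
    "SecondaryElectronRecord",
    "Track",
    "sample_free_path",
    "select_channel",
    "rudd_inversion_norm",
    "sample_ejected_electron",
    "sample_excitation_loss",
    "transport_primary",
    "read_psf",
    "write_psf",
    "write_deposits",
]

_REJECTION_GUARD = 100_000
_M_TO_NM = 1e9

#: channel code used for the residual energy deposited at the track endpoint
RESIDUAL_CHANNEL = -1


@dataclass
class ParticleState:
    """A primary ion's state: species (Z, A), energy, position and direction."""

    Z: int
    A: int
    Ek_eV: float
    position_nm: np.ndarray
    direction: np.ndarray
    particle_id: int = 0
    parent_id: int = -1

    def __post_init__(self) -> None:
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("direction must be a non-zero vector")
            self.direction = self.direction / norm
        if self.Ek_eV < 0:
            raise ValueError("kinetic energy must be >= 0")


@dataclass
class SecondaryElectronRecord:
    """An ejected electron handed to the phase-space stack, not transported."""

    Ee_eV: float
    position_nm: np.ndarray
    direction: np.ndarray
    parent_id: int


@dataclass
class Track:
    """The recorded history of one primary: deposits, secondaries, steps."""

    initial_Ek_eV: float
    particle_id: int
    deposit_positions_nm: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    deposit_energies_eV: np.ndarray = field(default_factory=lambda: np.empty(0))
    deposit_channels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    secondaries: list[SecondaryElectronRecord] = field(default_factory=list)
    step_losses_eV: np.ndarray = field(default_factory=lambda: np.empty(0))
    step_lengths_m: np.ndarray = field(default_factory=lambda: np.empty(0))
    start_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    end_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    termination: str = "cutoff"          # "cutoff" | "escaped"
    residual_eV: float = 0.0             # energy carried out when escaping

    @property
    def secondary_energy_eV(self) -> float:
        return float(sum(s.Ee_eV for s in self.secondaries))

    def energy_balance(self) -> float:
        """initial Ek minus (deposits + secondary energies + escaped residual)."""
        out = float(self.deposit_energies_eV.sum()) + self.secondary_energy_eV
        if self.termination == "escaped":
            out += self.residual_eV
        return self.initial_Ek_eV - out


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def sample_free_path(sigma_t: float, rng: np.random.Generator,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Exponential free-flight distance (m): s = -ln(zeta)/(n sigma_t)."""
    if sigma_t <= 0:
        raise ValueError("total cross-section must be positive")
    n = constants.water_number_density_m3
    zeta = rng.random()
    while zeta == 0.0:  # log(0) guard; measure-zero
        zeta = rng.random()
    return -math.log(zeta) / (n * sigma_t)


def select_channel(sigmas, rng: np.random.Generator) -> int:
    """Multinomial channel draw with probabilities sigma_i / sum(sigma)."""
    vals = sigmas.tolist() if isinstance(sigmas, np.ndarray) else list(sigmas)
    total = 0.0
    for s in vals:
        if s < 0:
            raise ValueError("cross-sections must be non-negative")
        total += s
    if total <= 0:
        raise ValueError("at least one channel cross-section must be positive")
    u = rng.random() * total
    acc = 0.0
    for i, s in enumerate(vals):
        acc += s
        if u < acc:
            return i
    return len(vals) - 1


def rudd_inversion_norm(F1: float, F2: float, wm: float) -> float:
    """Closed-form normalization Nc = int_0^wm (F1 + w F2)/(1+w)^3 dw."""
    return wm * (F2 * wm + 2.0 * F1 + F1 * wm) / (2.0 * (1.0 + wm) ** 2)


def _phi_scalar(w: float, alpha: float, wi: float, nu: float) -> float:
    arg = alpha * (w - wi) / nu
    if arg > 700.0:
        return 0.0
    if arg < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(arg))


def sample_ejected_electron(shell: str | ShellParams, Ek: float,
                            rng: np.random.Generator,
                            constants: PhysicalConstants = CONSTANTS,
                            ) -> tuple[float, float, float]:
    """Sample (Ee_eV, polar angle, azimuth) of the ejected electron.

    The scaled energy w is drawn from the smooth part of the Rudd SDCS by
    closed-form inversion and accepted against the sigmoid cutoff; the polar
    angle follows binary-encounter kinematics cos(theta) = sqrt(Ee/4T) for
    Ee > Bi and is uniform on [0, pi] otherwise.
    """
    sp = shell_params(shell) if isinstance(shell, str) else shell
    ctx = KinematicContext(Ek, sp, constants)
    F1, F2 = ctx.F1(), ctx.F2()
    wm = ctx.wm
    Nc = rudd_inversion_norm(F1, F2, wm)
    phi_max = _phi_scalar(0.0, sp.alpha, ctx.wi, ctx.nu)

    ws = 0.0
    for _ in range(_REJECTION_GUARD):
        c = Nc * rng.random()
        disc = F1 * F1 + 2.0 * F2 * c - 2.0 * F1 * c
        denom = F1 + F2 - 2.0 * c
        ws = (-F1 + 2.0 * c + math.sqrt(max(disc, 0.0))) / denom
        if _phi_scalar(ws, sp.alpha, ctx.wi, ctx.nu) > rng.random() * phi_max:
            break
    else:
        raise RuntimeError(
            "ejected-electron rejection loop exceeded the guard count; "
            "inconsistent shell parameters"
        )

    Ee = min(ws * sp.binding_eV, ctx.Em)
    if Ee > sp.binding_eV:
        cos_t = min(math.sqrt(Ee / (4.0 * ctx.T)), 1.0)
        theta = math.acos(cos_t)
    else:
        theta = rng.random() * math.pi
    phi = rng.random() * 2.0 * math.pi
    return Ee, theta, phi


def sample_excitation_loss(channel: str | ExcitationChannelHigh, Ek: float,
                           rng: np.random.Generator,
                           constants: PhysicalConstants = CONSTANTS) -> float:
    """Sample the energy loss W (eV) of a Born-regime excitation event.

    Gaussian channels draw W = w_j + zeta_n/sqrt(2 alpha_j) (resampled until
    inside [w_min, w_max]); the plasmon channel uses closed-form inversion of
    its sigmoid-derivative profile.  Both are accepted against
    g(W) = ln(4T/W)/W.
    """
    ch = load_excitation_high()[channel] if isinstance(channel, str) else channel
    T = constants.mass_ratio * Ek
    w_min, w_max = ch.w_min_eV, ch.w_max_eV
    if 4.0 * T <= w_max:
        raise ValueError("proton energy too low for the Born-regime excitation sampler")
    g_max = math.log(4.0 * T / w_min) / w_min

    alpha, wj = ch.alpha, ch.w_eV
    if ch.kind == "plasmon":
        u1 = 1.0 + math.exp(alpha * (w_min - wj))
        u2 = 1.0 + math.exp(alpha * (w_max - wj))
        Nc = (1.0 / u1 - 1.0 / u2) / alpha

    for _ in range(_REJECTION_GUARD):
        if ch.kind == "gaussian":
            Ws = wj + rng.standard_normal() / math.sqrt(2.0 * alpha)
            if not (w_min <= Ws <= w_max):
                continue
        else:
            zeta = rng.random()
            Ws = wj + math.log(u1 / (1.0 - alpha * u1 * Nc * zeta) - 1.0) / alpha
            Ws = min(max(Ws, w_min), w_max)
        g = math.log(4.0 * T / Ws) / Ws
        if g > rng.random() * g_max:
            return Ws
    raise RuntimeError(
        "excitation-loss rejection loop exceeded the guard count; "
        "inconsistent channel parameters"
    )


def _rotate_about(direction: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle theta, azimuth phi relative to `direction`."""
    dx, dy, dz = float(direction[0]), float(direction[1]), float(direction[2])
    # orthonormal frame around d (scalar math: this sits in the hot loop)
    if abs(dz) < 0.999:
        ax, ay, az = 0.0, 0.0, 1.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    e1x = dy * az - dz * ay
    e1y = dz * ax - dx * az
    e1z = dx * ay - dy * ax
    inv = 1.0 / math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x *= inv; e1y *= inv; e1z *= inv
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    return np.array([ct * dx + st * (cp * e1x + sp * e2x),
                     ct * dy + st * (cp * e1y + sp * e2y),
                     ct * dz + st * (cp * e1z + sp * e2z)])


# ---------------------------------------------------------------------------
# per-channel dispatch for a loaded table
# ---------------------------------------------------------------------------

class _ChannelSet:
    """Resolved sampler handles for every column of a cross-section table."""

    def __init__(self, table: CrossSectionTable):
        high = load_excitation_high()
        low = load_excitation_low()
        self.kinds: list[str] = []
        self.payload: list[object] = []
        for name, kind in zip(table.channels, table.kinds):
            self.kinds.append(kind)
            if kind == "ionization":
                self.payload.append(shell_params(name))
            elif kind == "excitation_low":
                self.payload.append(low[name.split(":", 1)[1]])
            elif kind == "excitation_high":
                self.payload.append(high[name.split(":", 1)[1]])
            else:
                raise ValueError(f"unknown channel kind {kind!r} in table")


# ---------------------------------------------------------------------------
# primary transport
# ---------------------------------------------------------------------------

def transport_primary(state: ParticleState, table: CrossSectionTable,
                      cutoff_eV: float = 1e3,
                      rng: np.random.Generator | None = None,
                      roi: Optional[Callable[[np.ndarray], bool]] = None,
                      constants: PhysicalConstants = CONSTANTS,
                      effective_charge_protons: bool = False) -> Track:
    """Transport one primary ion until cutoff or escape from the ROI.

    Per step: look up the proton cross-sections at Ep = Ek/A, scale the total
    by Zeff^2, fly an exponential free path, pick the channel, sample the
    collision outcome, deposit the local energy (binding energy or excitation
    loss) and append any secondary electron.  The primary travels in a
    straight line.  Residual sub-cutoff energy is deposited at the endpoint.

    The effective-charge scaling applies to ions with Z >= 2; the proton
    ionization model is an empirical fit to proton data that already contains
    the low-energy charge-exchange behaviour, so rescaling the proton by its
    own Booth factor would double-count it (and visibly lengthens sub-MeV
    ranges).  Set `effective_charge_protons=True` for the literal scaling.

    `roi`, when given, maps a position (nm) to True while the particle is
    inside the region of interest; leaving it terminates the track.
    """
    rng = np.random.default_rng() if rng is None else rng
    channels = _ChannelSet(table)
    e_min_table = 10.0 ** table.log10_grid[0]

    Z, A = state.Z, state.A
    Ek = float(state.Ek_eV)
    pos = state.position_nm.astype(float).copy()
    direction = state.direction / np.linalg.norm(state.direction)

    track = Track(initial_Ek_eV=Ek, particle_id=state.particle_id)
    track.start_nm = pos.copy()

    dep_pos: list[np.ndarray] = []
    dep_e: list[float] = []
    dep_ch: list[int] = []
    eps: list[float] = []
    lens: list[float] = []

    termination = "cutoff"
    while True:
        Ep = Ek / A
        if Ek <= cutoff_eV or Ep <= e_min_table:
            break
        sig = table.lookup(Ep).tolist()
        total = 0.0
        for v in sig:
            total += v
        if total <= 0.0:
            break
        if Z >= 2 or effective_charge_protons:
            zeff = effective_charge(Z, A, Ek, constants)
        else:
            zeff = 1.0
        sigma_t = zeff * zeff * total

        s = sample_free_path(sigma_t, rng, constants)
        pos = pos + (s * _M_TO_NM) * direction
        if roi is not None and not roi(pos):
            termination = "escaped"
            break

        idx = select_channel(sig, rng)
        kind = channels.kinds[idx]
        payload = channels.payload[idx]

        if kind == "ionization":
            sp: ShellParams = payload  # type: ignore[assignment]
            Ee, theta, phi = sample_ejected_electron(sp, Ep, rng, constants)
            loss = Ee + sp.binding_eV
            if loss >= Ek:
                # nearly stopped: deposit everything locally, no secondary
                dep_pos.append(pos.copy()); dep_e.append(Ek); dep_ch.append(idx)
                eps.append(Ek); lens.append(s)
                Ek = 0.0
                break
            dep_pos.append(pos.copy()); dep_e.append(sp.binding_eV); dep_ch.append(idx)
            track.secondaries.append(SecondaryElectronRecord(
                Ee_eV=Ee, position_nm=pos.copy(),
                direction=_rotate_about(direction, theta, phi),
                parent_id=state.particle_id,
            ))
            eps.append(loss); lens.append(s)
            Ek -= loss
        else:
            if kind == "excitation_high":
                W = sample_excitation_loss(payload, Ep, rng, constants)  # type: ignore[arg-type]
            else:
                W = payload.E_eV  # type: ignore[union-attr]
            W = min(W, Ek)
            dep_pos.append(pos.copy()); dep_e.append(W); dep_ch.append(idx)
            eps.append(W); lens.append(s)
            Ek -= W

    if termination == "cutoff" and Ek > 0.0:
        dep_pos.append(pos.copy()); dep_e.append(Ek); dep_ch.append(RESIDUAL_CHANNEL)
        Ek = 0.0
    track.residual_eV = Ek if termination == "escaped" else 0.0

    track.termination = termination
    track.end_nm = pos.copy()
    if dep_pos:
        track.deposit_positions_nm = np.asarray(dep_pos)
        track.deposit_energies_eV = np.asarray(dep_e)
        track.deposit_channels = np.asarray(dep_ch, dtype=int)
    track.step_losses_eV = np.asarray(eps)
    track.step_lengths_m = np.asarray(lens)
    return track


# ---------------------------------------------------------------------------
# phase-space and deposit files
# ---------------------------------------------------------------------------

_PSF_HEADER = "Z\tA\tE_eV\tx_nm\ty_nm\tz_nm\tux\tuy\tuz\tparent_id"


def write_psf(path: str | Path, particles: list[ParticleState],
              electrons: list[SecondaryElectronRecord] | None = None) -> None:
    """Write a tab-separated phase-space file; electrons carry Z=-1, A=0."""
    with Path(path).open("w") as fh:
        fh.write("# trackmc phase-space file\n")
        fh.write(_PSF_HEADER + "\n")
        for p in particles:
            x, y, z = p.position_nm
            ux, uy, uz = p.direction
            fh.write(f"{p.Z}\t{p.A}\t{p.Ek_eV:.8e}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t"
                     f"{ux:.9f}\t{uy:.9f}\t{uz:.9f}\t{p.parent_id}\n")
        for e in electrons or []:
            x, y, z = e.position_nm
            ux, uy, uz = e.direction
            fh.write(f"-1\t0\t{e.Ee_eV:.8e}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t"
                     f"{ux:.9f}\t{uy:.9f}\t{uz:.9f}\t{e.parent_id}\n")


def read_psf(path: str | Path) -> tuple[list[ParticleState], list[SecondaryElectronRecord]]:
    """Read a phase-space file back into primaries and electron records."""
    primaries: list[ParticleState] = []
    electrons: list[SecondaryElectronRecord] = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("Z\t"):
                continue
            parts = line.split("\t")
            Z, A = int(parts[0]), int(parts[1])
            E = float(parts[2])
            pos = np.array([float(p) for p in parts[3:6]])
            u = np.array([float(p) for p in parts[6:9]])
            parent = int(parts[9])
            if Z == -1:
                electrons.append(SecondaryElectronRecord(E, pos, u, parent))
            else:
                primaries.append(ParticleState(Z, A, E, pos, u,
                                               particle_id=len(primaries),
                                               parent_id=parent))
    return primaries, electrons


def write_deposits(path: str | Path, tracks: list[Track],
                   channel_names: list[str] | None = None,
                   metadata: dict | None = None) -> None:
    """Write all tracks' energy deposits as a tab-separated table."""
    with Path(path).open("w") as fh:
        fh.write("# trackmc energy deposits\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("x_nm\ty_nm\tz_nm\tenergy_eV\tchannel\tparticle_id\n")
        for t in tracks:
            for p, e, c in zip(t.deposit_positions_nm, t.deposit_energies_eV,
                               t.deposit_channels):
                name = ("residual" if c == RESIDUAL_CHANNEL
                        else (channel_names[c] if channel_names else str(c)))
                fh.write(f"{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\t{e:.6e}\t"
                         f"{name}\t{t.particle_id}\n")
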