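"""Proton-impact cross-sections for liquid water.

Implements the Rudd singly-differential ionization model for the five
molecular orbitals of water, the Born-regime three-channel excitation model
(two Gaussian discrete channels plus a plasmon channel) used above the model
switch energy, and the semi-empirical Miller-Green-form excitation model used
below it.  Builds and queries the per-channel lookup table on a uniform
log10-energy grid from 10 eV to 1 TeV.

Relativistic kinematics are used throughout; they reduce to the classical
expressions at low energy.
"""

from __future__ import annotations

import importlib.resources as _res
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import IntegrationWarning, quad

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "ShellParams",
    "KinematicContext",
    "ExcitationChannelHigh",
    "ExcitationChannelLow",
    "CrossSectionTable",
    "TableConfig",
    "load_shells",
    "shell_params",
    "inner_shell_labels",
    "load_excitation_high",
    "load_excitation_low",
    "max_transfer_energy",
    "rudd_sdcs",
    "ionization_xs",
    "excitation_sdcs_high",
    "excitation_xs_high",
    "excitation_xs_low",
    "build_tables",
    "lookup_xs",
]

SHELL_LABELS = ("1b1", "3a1", "1b2", "2a1", "1a1")

#: Default energy at which the excitation model switches from the
#: semi-empirical low-energy form to the Born-regime form.
DEFAULT_SWITCH_EV = 500e3

_GRID_LO_LOG10 = 1.0    # 10 eV
_GRID_HI_LOG10 = 12.0   # 1 TeV
_GRID_STEP_LOG10 = 0.01


def _data_path(name: str) -> Path:
    return Path(str(_res.files("trackmc").joinpath("data", name)))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellParams:
    """Rudd-model fit parameters for one molecular orbital of water."""

    label: str
    binding_eV: float
    n_electrons: int
    alpha: float
    A1: float
    B1: float
    C1: float
    D1: float
    E1: float
    A2: float
    B2: float
    C2: float
    D2: float

    def __post_init__(self) -> None:
        if self.binding_eV <= 0 or self.n_electrons <= 0 or self.alpha <= 0:
            raise ValueError(f"invalid shell parameters for {self.label}")


@dataclass(frozen=True)
class ExcitationChannelHigh:
    """Born-regime excitation channel (Gaussian or plasmon profile)."""

    label: str
    kind: str              # "gaussian" | "plasmon"
    f0: float
    alpha: float           # eV^-2 (gaussian) or eV^-1 (plasmon)
    w_eV: float            # profile centre
    smooth: float          # continuity coefficient applied to the total XS
    w_min_eV: float = 2.0
    w_max_eV: float = 50.0

    def profile(self, W: np.ndarray | float) -> np.ndarray | float:
        """Oscillator-strength density f_j(W)."""
        W = np.asarray(W, dtype=float)
        if self.kind == "gaussian":
            return self.f0 * math.sqrt(self.alpha / math.pi) * np.exp(
                -self.alpha * (W - self.w_eV) ** 2
            )
        x = np.clip(self.alpha * (W - self.w_eV), -700.0, 700.0)
        ex = np.exp(x)
        return self.f0 * self.alpha * ex / (1.0 + ex) ** 2


@dataclass(frozen=True)
class ExcitationChannelLow:
    """Semi-empirical low-energy excitation channel with discrete loss E_j."""

    label: str
    E_eV: float
    sigma0_m2: float
    za: float
    J_eV: float
    omega: float
    nu: float

    def __post_init__(self) -> None:
        if self.E_eV <= 0 or self.sigma0_m2 <= 0 or self.J_eV <= 0:
            raise ValueError(f"invalid low-energy channel {self.label}")

    def cross_section(self, Ek: float) -> float:
        if Ek <= self.E_eV:
            return 0.0
        p = self.omega + self.nu
        return (
            self.sigma0_m2
            * self.za ** self.omega
            * (Ek - self.E_eV) ** self.nu
            / (self.J_eV ** p + Ek ** p)
        )


# ---------------------------------------------------------------------------
# parameter file loading
# ---------------------------------------------------------------------------

def load_shells(path: str | Path | None = None) -> dict[str, ShellParams]:
    """Load the Rudd shell parameter file and validate its invariants."""
    path = _data_path("rudd_shells.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())["shells"]
    if set(raw) != set(SHELL_LABELS):
        raise ValueError(f"shell file must define exactly {SHELL_LABELS}")
    shells = {
        label: ShellParams(label=label, **vals) for label, vals in raw.items()
    }
    return shells


_SHELLS: dict[str, ShellParams] | None = None


def _shells() -> dict[str, ShellParams]:
    global _SHELLS
    if _SHELLS is None:
        _SHELLS = load_shells()
    return _SHELLS


def shell_params(label: str) -> ShellParams:
    """Return the fit parameters for one shell; raise on unknown labels."""
    shells = _shells()
    if label not in shells:
        raise KeyError(
            f"unknown shell {label!r}; valid labels are {', '.join(SHELL_LABELS)}"
        )
    return shells[label]


def inner_shell_labels(shells: Mapping[str, ShellParams] | None = None) -> set[str]:
    """Shells whose binding energy exceeds twice the smallest binding energy."""
    shells = _shells() if shells is None else dict(shells)
    b_min = min(s.binding_eV for s in shells.values())
    return {s.label for s in shells.values() if s.binding_eV > 2.0 * b_min}


def load_excitation_high(
    path: str | Path | None = None,
) -> dict[str, ExcitationChannelHigh]:
    path = _data_path("excitation_high.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    w_min, w_max = float(raw["w_min_eV"]), float(raw["w_max_eV"])
    out = {}
    for label, vals in raw["channels"].items():
        ch = ExcitationChannelHigh(
            label=label, kind=vals["kind"], f0=vals["f0"], alpha=vals["alpha"],
            w_eV=vals["w_eV"], smooth=vals["smooth"],
            w_min_eV=w_min, w_max_eV=w_max,
        )
        if not (w_min < ch.w_eV < w_max):
            raise ValueError(f"channel centre of {label} outside [{w_min},{w_max}] eV")
        out[label] = ch
    return out


def load_excitation_low(
    path: str | Path | None = None,
) -> dict[str, ExcitationChannelLow]:
    path = _data_path("excitation_low.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())["channels"]
    return {label: ExcitationChannelLow(label=label, **vals) for label, vals in raw.items()}


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def max_transfer_energy(Ek: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Maximum energy transferable to a free electron by a proton of energy Ek.

    Relativistic expression; tends to 4*(m/M)*Ek in the nonrelativistic limit.
    """
    if Ek <= 0:
        raise ValueError("proton kinetic energy must be positive")
    r = constants.mass_ratio
    eps = Ek / constants.proton_rest_energy_eV
    gamma = 1.0 + eps
    gamma2_m1 = eps * (2.0 + eps)  # gamma^2 - 1 without cancellation
    return (
        2.0 * constants.electron_rest_energy_eV * gamma2_m1
        / (1.0 + 2.0 * gamma * r + r**2)
    )


class KinematicContext:
    """Per-energy, per-shell kinematic quantities of the Rudd model.

    Houses the Lorentz factor, scaled energy T = (m/M)*Ek, maximum transfer
    Em, and the per-shell scaled velocity nu, cutoff w_i, upper bound w_m and
    shell strength S_i.
    """

    __slots__ = ("Ek", "gamma", "T", "Em", "shell", "nu", "nu2", "wi", "wm", "Si")

    def __init__(self, Ek: float, shell: ShellParams,
                 constants: PhysicalConstants = CONSTANTS):
        if Ek <= 0:
            raise ValueError("proton kinetic energy must be positive")
        self.Ek = Ek
        self.shell = shell
        mc2 = constants.electron_rest_energy_eV
        eps = Ek / constants.proton_rest_energy_eV
        self.gamma = 1.0 + eps
        self.T = constants.mass_ratio * Ek
        self.Em = max_transfer_energy(Ek, constants)
        B = shell.binding_eV
        # 1 - gamma^-2 = (gamma^2 - 1)/gamma^2, cancellation-free
        self.nu2 = (mc2 / (2.0 * B)) * eps * (2.0 + eps) / self.gamma**2
        self.nu = math.sqrt(self.nu2)
        self.wi = 4.0 * self.nu2 - 2.0 * self.nu - constants.rydberg_eV / (4.0 * B)
        self.wm = self.Em / B
        self.Si = (
            4.0 * math.pi * constants.bohr_radius_m**2
            * shell.n_electrons * (constants.rydberg_eV / B) ** 2
        )

    def F1(self) -> float:
        s = self.shell
        n2 = self.nu2
        L1 = s.C1 * self.nu**s.D1 / (1.0 + s.E1 * self.nu ** (s.D1 + 4.0))
        H1 = s.A1 * math.log1p(n2) / (n2 + s.B1 / n2)
        return L1 + H1

    def F2(self) -> float:
        s = self.shell
        L2 = s.C2 * self.nu**s.D2
        H2 = s.A2 / self.nu2 + s.B2 / self.nu2**2
        return L2 * H2 / (L2 + H2)


def _rudd_f(w: np.ndarray | float, F1: float, F2: float) -> np.ndarray | float:
    """Smooth part (F1 + w F2)/(1+w)^3 of the Rudd SDCS."""
    w = np.asarray(w, dtype=float)
    return (F1 + w * F2) / (1.0 + w) ** 3


def _rudd_phi(w: np.ndarray | float, alpha: float, wi: float, nu: float):
    """Sigmoid cutoff 1/(1 + exp(alpha (w - wi)/nu)) of the Rudd SDCS."""
    w = np.asarray(w, dtype=float)
    arg = np.clip(alpha * (w - wi) / nu, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(arg))


def rudd_sdcs(shell: str | ShellParams, Ek: float, w: np.ndarray | float,
              constants: PhysicalConstants = CONSTANTS):
    """Rudd SDCS dsigma/dw (m^2 per unit scaled electron energy w = Ee/Bi)."""
    sp = shell_params(shell) if isinstance(shell, str) else shell
    ctx = KinematicContext(Ek, sp, constants)
    f = _rudd_f(w, ctx.F1(), ctx.F2())
    phi = _rudd_phi(w, sp.alpha, ctx.wi, ctx.nu)
    return ctx.Si * f * phi


def ionization_xs(shell: str | ShellParams, Ek: float,
                  constants: PhysicalConstants = CONSTANTS,
                  rtol: float = 1e-6) -> float:
    """Total ionization cross-section (m^2) of one shell at proton energy Ek.

    Adaptive quadrature of the SDCS over the scaled energy range [0, w_m].
    """
    if not (10.0 <= Ek <= 1e12):
        raise ValueError("proton energy must lie in the tabulated range 10 eV .. 1 TeV")
    sp = shell_params(shell) if isinstance(shell, str) else shell
    ctx = KinematicContext(Ek, sp, constants)
    F1, F2 = ctx.F1(), ctx.F2()

    def integrand(w: float) -> float:
        return float(_rudd_f(w, F1, F2) * _rudd_phi(w, sp.alpha, ctx.wi, ctx.nu))

    pts = [ctx.wi] if 0.0 < ctx.wi < ctx.wm else None
    with warnings.catch_warnings():
        # near-threshold energies leave an all-but-zero integrand that quad
        # flags as slowly convergent; the value itself is fine
        warnings.simplefilter("ignore", IntegrationWarning)
        val, _ = quad(integrand, 0.0, ctx.wm, points=pts, epsrel=rtol,
                      epsabs=0.0, limit=200)
    return ctx.Si * val


# ---------------------------------------------------------------------------
# excitation, high-energy regime
# ---------------------------------------------------------------------------

def _bethe_prefactor(W, Ek: float, constants: PhysicalConstants):
    """rho(W) = 8 pi Z^2 a0^2 Ry^2 / (m u^2 W^2) for a proton (Z = 1), m^2/eV^3."""
    gamma = 1.0 + Ek / constants.proton_rest_energy_eV
    mu2 = constants.electron_rest_energy_eV * (1.0 - 1.0 / gamma**2)
    W = np.asarray(W, dtype=float)
    return (
        8.0 * math.pi * constants.bohr_radius_m**2 * constants.rydberg_eV**2
        / (mu2 * W**2)
    )


def excitation_sdcs_high(channel: str | ExcitationChannelHigh, Ek: float,
                         W: np.ndarray | float,
                         constants: PhysicalConstants = CONSTANTS):
    """Born-regime excitation SDCS dsigma/dW (m^2/eV) at energy loss W."""
    ch = load_excitation_high()[channel] if isinstance(channel, str) else channel
    T = constants.mass_ratio * Ek
    Wa = np.asarray(W, dtype=float)
    if np.any(4.0 * T <= Wa):
        raise ValueError("invalid kinematic regime: 4T must exceed the energy loss W")
    return _bethe_prefactor(Wa, Ek, constants) * Wa * ch.profile(Wa) * np.log(4.0 * T / Wa)


def excitation_xs_high(channel: str | ExcitationChannelHigh, Ek: float,
                       constants: PhysicalConstants = CONSTANTS,
                       switch_eV: float = DEFAULT_SWITCH_EV,
                       rtol: float = 1e-6) -> float:
    """Total Born-regime excitation cross-section (m^2), smoothing applied.

    Integrates the SDCS over [w_min, w_max] (2..50 eV) and multiplies by the
    channel's continuity coefficient.
    """
    ch = load_excitation_high()[channel] if isinstance(channel, str) else channel
    if Ek < switch_eV:
        raise ValueError(
            f"Ek = {Ek:g} eV is below the model switch energy {switch_eV:g} eV; "
            "use excitation_xs_low"
        )

    def integrand(W: float) -> float:
        return float(excitation_sdcs_high(ch, Ek, W, constants))

    val, _ = quad(integrand, ch.w_min_eV, ch.w_max_eV,
                  points=[ch.w_eV], epsrel=rtol, epsabs=0.0, limit=200)
    return ch.smooth * val


def excitation_xs_low(channel: str | ExcitationChannelLow, Ek: float,
                      channels: Mapping[str, ExcitationChannelLow] | None = None) -> float:
    """Semi-empirical low-energy excitation cross-section (m^2); 0 below threshold."""
    if isinstance(channel, str):
        channels = load_excitation_low() if channels is None else channels
        if channel not in channels:
            raise KeyError(
                f"unknown low-energy excitation channel {channel!r}; the parameter "
                "file data/excitation_low.yaml defines " + ", ".join(channels)
            )
        channel = channels[channel]
    if Ek <= 0:
        raise ValueError("proton kinetic energy must be positive")
    return channel.cross_section(Ek)


# ---------------------------------------------------------------------------
# lookup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableConfig:
    """Configuration of a cross-section table build."""

    switch_eV: float = DEFAULT_SWITCH_EV
    #: apply the low-energy excitation model all the way up to 80 MeV
    low_model_to_80MeV: bool = False
    model_version: str = "trackmc-1"

    @property
    def excitation_boundary_eV(self) -> float:
        return 80e6 if self.low_model_to_80MeV else self.switch_eV


class CrossSectionTable:
    """Per-channel cross-sections (m^2) on a uniform log10-energy grid.

    Columns: the five ionization shells, the five low-energy excitation
    channels (zero above the model boundary) and the three high-energy
    excitation channels (zero below it).
    """

    def __init__(self, log10_grid: np.ndarray, channels: Sequence[str],
                 kinds: Sequence[str], values: np.ndarray, config: TableConfig):
        if values.shape != (log10_grid.size, len(channels)):
            raise ValueError("table shape mismatch")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("cross-section table entries must be finite and >= 0")
        if np.any(np.diff(log10_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        self.log10_grid = log10_grid
        self.channels = tuple(channels)
        self.kinds = tuple(kinds)   # "ionization" | "excitation_low" | "excitation_high"
        self.values = values
        self.config = config

    @property
    def energies_eV(self) -> np.ndarray:
        return 10.0 ** self.log10_grid

    # -- query --------------------------------------------------------------

    def lookup(self, Ek: float) -> np.ndarray:
        """Per-channel cross-sections at Ek, linear interpolation in log10(E)."""
        lo, hi = self.log10_grid[0], self.log10_grid[-1]
        x = math.log10(Ek) if Ek > 0 else -math.inf
        if not (lo <= x <= hi):
            raise ValueError(
                f"Ek = {Ek:g} eV outside the tabulated range "
                f"[{10.0**lo:g}, {10.0**hi:g}] eV"
            )
        step = self.log10_grid[1] - self.log10_grid[0]
        pos = (x - lo) / step
        nearest = round(pos)
        if abs(pos - nearest) < 1e-9 and 0 <= nearest < self.log10_grid.size:
            return self.values[int(nearest)].copy()  # node-exact
        i = min(int(pos), self.log10_grid.size - 2)
        frac = pos - i
        row = self.values[i]
        return row + frac * (self.values[i + 1] - row)

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the table as tab-separated text with a '#' metadata header."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# trackmc cross-section table\n")
            fh.write("# unit: m^2\n")
            fh.write(f"# model_version: {self.config.model_version}\n")
            fh.write(f"# switch_eV: {self.config.switch_eV:.6g}\n")
            fh.write(f"# low_model_to_80MeV: {self.config.low_model_to_80MeV}\n")
            fh.write("# kinds: " + "\t".join(self.kinds) + "\n")
            fh.write("log10_E_eV\t" + "\t".join(self.channels) + "\n")
            for x, row in zip(self.log10_grid, self.values):
                fh.write(f"{x:.2f}\t" + "\t".join(f"{v:.10e}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CrossSectionTable":
        path = Path(path)
        meta: dict[str, str] = {}
        rows = []
        header: list[str] = []
        with path.open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if ":" in line:
                        key, _, val = line[1:].partition(":")
                        meta[key.strip()] = val.strip()
                    continue
                parts = line.split("\t")
                if not header:
                    header = parts
                    continue
                rows.append([float(p) for p in parts])
        arr = np.asarray(rows, dtype=float)
        config = TableConfig(
            switch_eV=float(meta.get("switch_eV", DEFAULT_SWITCH_EV)),
            low_model_to_80MeV=meta.get("low_model_to_80MeV", "False") == "True",
            model_version=meta.get("model_version", "unknown"),
        )
        kinds = tuple(meta.get("kinds", "").split("\t")) if meta.get("kinds") else ()
        return cls(arr[:, 0], header[1:], kinds, arr[:, 1:], config)


def build_tables(config: TableConfig | None = None,
                 constants: PhysicalConstants = CONSTANTS,
                 log10_step: float = _GRID_STEP_LOG10) -> CrossSectionTable:
    """Build the full cross-section table on the 10 eV .. 1 TeV log grid.

    Ionization channels are tabulated at every grid energy; excitation
    channels come from the low-energy model below the model boundary and the
    smoothed Born-regime model above it.
    """
    config = TableConfig() if config is None else config
    n = round((_GRID_HI_LOG10 - _GRID_LO_LOG10) / log10_step) + 1
    grid = _GRID_LO_LOG10 + log10_step * np.arange(n)
    energies = 10.0 ** grid

    shells = _shells()
    high = load_excitation_high()
    low = load_excitation_low()
    boundary = config.excitation_boundary_eV

    channels = (
        list(SHELL_LABELS)
        + [f"exc_low:{c}" for c in low]
        + [f"exc_high:{c}" for c in high]
    )
    kinds = (
        ["ionization"] * len(SHELL_LABELS)
        + ["excitation_low"] * len(low)
        + ["excitation_high"] * len(high)
    )
    values = np.zeros((n, len(channels)))

    for j, label in enumerate(SHELL_LABELS):
        sp = shells[label]
        values[:, j] = [ionization_xs(sp, Ek, constants) for Ek in energies]

    off = len(SHELL_LABELS)
    for j, ch in enumerate(low.values()):
        col = np.array([ch.cross_section(Ek) for Ek in energies])
        col[energies >= boundary] = 0.0
        values[:, off + j] = col

    off += len(low)
    for j, ch in enumerate(high.values()):
        mask = energies >= boundary
        col = np.zeros(n)
        col[mask] = [
            excitation_xs_high(ch, Ek, constants, switch_eV=boundary)
            for Ek in energies[mask]
        ]
        values[:, off + j] = col

    return CrossSectionTable(grid, channels, kinds, values, config)


def lookup_xs(table: CrossSectionTable, Ek: float) -> np.ndarray:
    """Per-channel cross-section vector at proton energy Ek (module-level alias)."""
    return table.lookup(Ek)
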