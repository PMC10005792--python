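"""Lorentzian relaxation model for ¹H spin-lattice dispersion profiles.

The spin-lattice relaxation rate of a proton-rich soft material measured
over a wide Larmor-frequency range (fast-field-cycling relaxometry) is
described as a sum of Lorentzian spectral-density contributions

    R1(ω) = Σ_k C_k^DD [ τ_k / (1 + (ω τ_k)²) + 4 τ_k / (1 + (2 ω τ_k)²) ] + A

where each component k has a dipolar relaxation constant ``C_k^DD`` (Hz²,
i.e. s⁻²) setting the strength of the fluctuating ¹H–¹H dipole–dipole
couplings, and a correlation time ``τ_k`` (s) setting the timescale of the
motion that modulates them.  ``A`` (s⁻¹) is a frequency-independent offset
from motions far faster than the probed window.  Public interfaces take the
Larmor frequency ν in Hz; ω = 2πν is applied internally.

For jelly-candy-like hydrogels three components suffice, labelled *slow*
(~10⁻⁶ s, macromolecular network), *intermediate* (~10⁻⁷ s, confined
water) and *fast* (~10⁻⁸ s, loosely bound water); up to four are supported
so that over-parameterization can be probed by model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "COMPONENT_LABELS",
    "PARAM_NAMES",
    "SpectralComponent",
    "RelaxationModel",
    "FrequencyGrid",
    "Decomposition",
    "lorentzian_bracket",
    "evaluate_r1",
    "decompose",
    "read_params_json",
    "write_params_json",
]

COMPONENT_LABELS = ("slow", "intermediate", "fast", "other")

#: Canonical parameter names of the three-component model, in table order.
PARAM_NAMES = ("c_s_dd", "tau_s", "c_i_dd", "tau_i", "c_f_dd", "tau_f", "a")

#: Labels assigned by descending-τ rank for each supported component count.
_RANK_LABELS = {
    1: ("other",),
    2: ("slow", "fast"),
    3: ("slow", "intermediate", "fast"),
    4: ("slow", "intermediate", "fast", "other"),
}


def lorentzian_bracket(tau, omega):
    """Bracketed spectral-density term ``τ/(1+(ωτ)²) + 4τ/(1+(2ωτ)²)``.

    Parameters
    ----------
    tau : float
        Correlation time in seconds, strictly positive.
    omega : float or array-like
        Angular frequency in rad/s, non-negative.

    Returns
    -------
    float or ndarray
        Bracket value in seconds.  Equals ``5·tau`` at ``omega = 0`` and is
        strictly decreasing in ``omega``.
    """
    tau = float(tau)
    if not np.isfinite(tau) or tau <= 0.0:
        raise ValueError(f"correlation time must be finite and > 0, got {tau!r}")
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0) or not np.all(np.isfinite(omega)):
        raise ValueError("angular frequency must be finite and >= 0")
    wt = omega * tau
    out = tau / (1.0 + wt * wt) + 4.0 * tau / (1.0 + 4.0 * wt * wt)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SpectralComponent:
    """One Lorentzian relaxation contribution.

    Attributes
    ----------
    c_dd : float
        Dipolar relaxation constant in Hz² (s⁻²); non-negative.
    tau : float
        Correlation time in seconds; strictly positive.
    label : str
        One of ``slow``, ``intermediate``, ``fast``, ``other``.
    """

    c_dd: float
    tau: float
    label: str = "other"

    def __post_init__(self):
        if not (np.isfinite(self.c_dd) and self.c_dd >= 0.0):
            raise ValueError(f"c_dd must be finite and >= 0, got {self.c_dd!r}")
        if not (np.isfinite(self.tau) and self.tau > 0.0):
            raise ValueError(f"tau must be finite and > 0, got {self.tau!r}")
        if self.label not in COMPONENT_LABELS:
            raise ValueError(f"label must be one of {COMPONENT_LABELS}, got {self.label!r}")

    def r1(self, freqs_hz) -> np.ndarray:
        """Contribution of this component to R1 at Larmor frequencies ν (Hz)."""
        omega = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float)
        return self.c_dd * lorentzian_bracket(self.tau, omega)


@dataclass(frozen=True)
class RelaxationModel:
    """Ordered set of spectral components plus a frequency-independent offset.

    Components are stored sorted by strictly decreasing correlation time
    (slow first); labels must be unique.  ``offset_a`` is in s⁻¹.
    """

    components: tuple
    offset_a: float = 0.0

    def __post_init__(self):
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 4:
            raise ValueError(f"model must have 1-4 components, got {len(comps)}")
        taus = [c.tau for c in comps]
        if any(t2 >= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("components must be sorted by strictly decreasing tau")
        labels = [c.label for c in comps]
        if len(set(labels)) != len(labels):
            raise ValueError(f"component labels must be unique, got {labels}")
        if not (np.isfinite(self.offset_a) and self.offset_a >= 0.0):
            raise ValueError(f"offset_a must be finite and >= 0, got {self.offset_a!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_components(cls, c_dd: Sequence[float], tau: Sequence[float],
                        offset_a: float = 0.0) -> "RelaxationModel":
        """Build from parallel C/τ arrays; sorts by descending τ and labels by rank."""
        if len(c_dd) != len(tau):
            raise ValueError("c_dd and tau must have equal length")
        order = np.argsort(tau)[::-1]
        labels = _RANK_LABELS[len(order)]
        comps = tuple(
            SpectralComponent(float(c_dd[i]), float(tau[i]), labels[j])
            for j, i in enumerate(order)
        )
        return cls(comps, float(offset_a))

    @classmethod
    def from_params(cls, params: Mapping[str, float]) -> "RelaxationModel":
        """Build the canonical three-component model from a flat parameter map.

        Expects keys ``c_s_dd, tau_s, c_i_dd, tau_i, c_f_dd, tau_f, a``.
        """
        missing = [k for k in PARAM_NAMES if k not in params]
        if missing:
            raise KeyError(f"missing parameters: {missing}")
        comps = (
            SpectralComponent(float(params["c_s_dd"]), float(params["tau_s"]), "slow"),
            SpectralComponent(float(params["c_i_dd"]), float(params["tau_i"]), "intermediate"),
            SpectralComponent(float(params["c_f_dd"]), float(params["tau_f"]), "fast"),
        )
        return cls(comps, float(params["a"]))

    # -- accessors ---------------------------------------------------------
    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def c_dd(self) -> np.ndarray:
        return np.array([c.c_dd for c in self.components])

    @property
    def tau(self) -> np.ndarray:
        return np.array([c.tau for c in self.components])

    def to_params(self) -> dict:
        """Flat canonical parameter map (three-component models only)."""
        if self.n_components != 3:
            raise ValueError("canonical parameter map requires exactly 3 components")
        by_label = {c.label: c for c in self.components}
        return {
            "c_s_dd": by_label["slow"].c_dd,
            "tau_s": by_label["slow"].tau,
            "c_i_dd": by_label["intermediate"].c_dd,
            "tau_i": by_label["intermediate"].tau,
            "c_f_dd": by_label["fast"].c_dd,
            "tau_f": by_label["fast"].tau,
            "a": self.offset_a,
        }

    def r1(self, freqs_hz) -> np.ndarray:
        return evaluate_r1(self, freqs_hz)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive ¹H Larmor frequencies ν in Hz."""

    freqs_hz: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        f.setflags(write=False)
        object.__setattr__(self, "freqs_hz", f)

    @classmethod
    def log_spaced(cls, f_min: float = 1e4, f_max: float = 1e7,
                   n: int = 32) -> "FrequencyGrid":
        """Log-spaced grid; defaults span the 10 kHz–10 MHz relaxometry window."""
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ω = 2πν in rad/s."""
        return 2.0 * np.pi * self.freqs_hz

    def __len__(self) -> int:
        return self.freqs_hz.size


def _as_freqs(grid) -> np.ndarray:
    if isinstance(grid, FrequencyGrid):
        return grid.freqs_hz
    f = np.asarray(grid, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency grid")
    return f


def evaluate_r1(model: RelaxationModel, grid) -> np.ndarray:
    """Total R1(ν) in s⁻¹ over a frequency grid (ν in Hz)."""
    freqs = _as_freqs(grid)
    omega = 2.0 * np.pi * freqs
    out = np.full(omega.shape, float(model.offset_a))
    for comp in model.components:
        out = out + comp.c_dd * lorentzian_bracket(comp.tau, omega)
    return out


@dataclass(frozen=True)
class Decomposition:
    """Per-process R1 contributions plus the constant offset.

    ``curves`` maps component label → R1 contribution (s⁻¹) on the grid;
    their sum plus ``offset_a`` reconstructs the total rate exactly.
    """

    freqs_hz: np.ndarray
    curves: dict
    offset_a: float

    @property
    def total(self) -> np.ndarray:
        out = np.full(self.freqs_hz.shape, self.offset_a)
        for curve in self.curves.values():
            out = out + curve
        return out


def decompose(model: RelaxationModel, grid) -> Decomposition:
    """Split R1(ν) into per-component curves (e.g. R1s, R1i, R1f) plus A."""
    freqs = _as_freqs(grid)
    omega = 2.0 * np.pi * freqs
    curves = {
        comp.label: comp.c_dd * lorentzian_bracket(comp.tau, omega)
        for comp in model.components
    }
    return Decomposition(freqs_hz=freqs, curves=curves, offset_a=float(model.offset_a))


# -- flat JSON parameter documents ----------------------------------------
#
# The on-disk form is a flat map of the canonical names to either a bare
# number/decimal string or an object {"value": ..., "uncertainty": ...,
# "fixed": true}.  Values given as decimal strings are preserved verbatim on
# round-trip so that published table entries survive bit-exactly.


def read_params_json(path) -> tuple:
    """Read a flat parameter document; returns ``(RelaxationModel, raw_dict)``."""
    with open(path) as fh:
        raw = json.load(fh)
    values = {}
    for name in PARAM_NAMES:
        if name not in raw:
            raise KeyError(f"parameter file {path} missing {name!r}")
        entry = raw[name]
        values[name] = float(entry["value"] if isinstance(entry, dict) else entry)
    return RelaxationModel.from_params(values), raw


def write_params_json(path, params: Mapping, *, extra: Mapping | None = None) -> None:
    """Write a flat parameter document.

    ``params`` maps canonical names to numbers, decimal strings, or
    ``{"value": ..., "uncertainty": ..., "fixed": ...}`` objects, which are
    written through unchanged.
    """
    doc = {name: params[name] for name in PARAM_NAMES}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
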