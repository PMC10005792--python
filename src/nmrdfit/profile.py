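"""NMRD profile container and its plain-CSV interchange format.

A profile is one (sample, temperature) relaxation-dispersion dataset:
Larmor frequencies in Hz, spin-lattice rates R1 in s⁻¹, optional 1σ
uncertainties, and per-point censoring flags marking rates that were too
fast to measure (excluded from all fitting and comparison).

CSV dialect: comma-separated, UTF-8, ``#``-prefixed metadata lines of the
form ``# key = value`` before the header, mandatory header
``frequency_hz,r1_per_s[,r1_err_per_s][,censored]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["NMRDProfile", "read_profile_csv", "write_profile_csv", "ProfileFormatError"]


class ProfileFormatError(ValueError):
    """Raised when a profile CSV cannot be parsed."""


@dataclass
class NMRDProfile:
    """One sample × temperature relaxation dispersion dataset."""

    sample_id: str
    temperature_k: float
    freqs_hz: np.ndarray
    r1: np.ndarray
    r1_err: np.ndarray | None = None
    censored: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        n = self.freqs_hz.size
        if self.freqs_hz.ndim != 1 or n == 0:
            raise ValueError("freqs_hz must be a non-empty 1-D array")
        if np.any(self.freqs_hz <= 0) or np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be positive and strictly increasing")
        if self.r1.shape != self.freqs_hz.shape:
            raise ValueError("r1 and freqs_hz lengths disagree")
        if self.r1_err is not None:
            self.r1_err = np.asarray(self.r1_err, dtype=float)
            if self.r1_err.shape != self.freqs_hz.shape:
                raise ValueError("r1_err and freqs_hz lengths disagree")
            if np.any(self.r1_err < 0):
                raise ValueError("r1_err must be >= 0")
        if self.censored is None:
            self.censored = np.zeros(n, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
            if self.censored.shape != self.freqs_hz.shape:
                raise ValueError("censored and freqs_hz lengths disagree")
        if np.any(self.r1[~self.censored] <= 0):
            raise ValueError("uncensored R1 values must be > 0")
        if not np.all(np.isfinite(self.r1[~self.censored])):
            raise ValueError("uncensored R1 values must be finite")

    # -- views -------------------------------------------------------------
    @property
    def uncensored(self) -> np.ndarray:
        """Boolean mask of points usable for fitting."""
        return ~self.censored

    @property
    def n_uncensored(self) -> int:
        return int(self.uncensored.sum())

    @property
    def span_hz(self) -> tuple:
        """(min, max) frequency of the uncensored points."""
        f = self.freqs_hz[self.uncensored]
        if f.size == 0:
            raise ValueError(f"profile {self.sample_id!r} has no uncensored points")
        return float(f[0]), float(f[-1])

    def key(self) -> tuple:
        return (self.sample_id, float(self.temperature_k))


def write_profile_csv(path, profile: NMRDProfile) -> None:
    """Write one profile in the package CSV dialect."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_id = {profile.sample_id}\n")
        fh.write(f"# temperature_k = {profile.temperature_k:g}\n")
        for key, value in sorted(profile.meta.items()):
            fh.write(f"# {key} = {value}\n")
        cols = {"frequency_hz": profile.freqs_hz, "r1_per_s": profile.r1}
        if profile.r1_err is not None:
            cols["r1_err_per_s"] = profile.r1_err
        cols["censored"] = profile.censored.astype(int)
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.12g")


def read_profile_csv(path) -> NMRDProfile:
    """Read one profile; raises :class:`ProfileFormatError` naming the file."""
    meta: dict = {}
    body_lines = []
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#"):
                    text = line[1:].strip()
                    if "=" in text:
                        key, _, value = text.partition("=")
                        meta[key.strip()] = value.strip()
                    continue
                body_lines.append(line)
    except OSError as exc:
        raise ProfileFormatError(f"{path}: {exc}") from exc
    if not body_lines:
        raise ProfileFormatError(f"{path}: no data rows")
    try:
        frame = pd.read_csv(io.StringIO("".join(body_lines)))
    except Exception as exc:
        raise ProfileFormatError(f"{path}: malformed CSV ({exc})") from exc
    for col in ("frequency_hz", "r1_per_s"):
        if col not in frame.columns:
            raise ProfileFormatError(f"{path}: missing required column {col!r}")
    sample_id = meta.pop("sample_id", None)
    temperature = meta.pop("temperature_k", None)
    if sample_id is None or temperature is None:
        raise ProfileFormatError(
            f"{path}: metadata lines '# sample_id = ...' and "
            f"'# temperature_k = ...' are required"
        )
    try:
        return NMRDProfile(
            sample_id=sample_id,
            temperature_k=float(temperature),
            freqs_hz=frame["frequency_hz"].to_numpy(),
            r1=frame["r1_per_s"].to_numpy(),
            r1_err=(frame["r1_err_per_s"].to_numpy()
                    if "r1_err_per_s" in frame.columns else None),
            censored=(frame["censored"].to_numpy().astype(bool)
                      if "censored" in frame.columns else None),
            meta=meta,
        )
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: {exc}") from exc
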