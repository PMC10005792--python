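"""Constrained fitting of Lorentzian dispersion models to NMRD profiles.

Single-profile fits, shared-parameter global fits across samples and
temperatures, a greedy parsimony search that explains differences between
profiles with as few freed parameters as possible, and AIC-based selection
of the number of relaxation components.

Numerical conventions
---------------------
* Dipolar constants and correlation times are optimized in log10 space
  (positivity, and the scales span 10⁻⁹–10⁻⁶ s and 10⁷–10⁹ Hz²); the
  offset A is optimized linearly with a lower bound of 0.
* Residuals are weighted by the supplied 1σ uncertainties when present,
  otherwise relatively (σᵢ = R1ᵢ), since profiles span about two decades.
* Each fit is a seeded multi-start: correlation times start on the decades
  10⁻⁶/10⁻⁷/10⁻⁸ s, dipolar constants from a magnitude heuristic, with
  log-space jitter on subsequent starts.
* Censored points are excluded, never imputed.
* AIC = n·ln(χ²/n) + 2p; ties within 2 AIC units resolve toward fewer
  free parameters or fewer components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .constraints import Constraint, ConstraintMap, free
from .model import PARAM_NAMES, RelaxationModel, evaluate_r1
from .profile import NMRDProfile
from .recovery import FitConvergenceError, InsufficientDataError

__all__ = [
    "GlobalFitResult",
    "ParsimonyResult",
    "LorentzianDispersionFitter",
    "GlobalDispersionFitter",
    "ComponentSelector",
    "ParsimonySearch",
    "DegenerateComponentsWarning",
    "RankDeficiencyWarning",
    "fit_single",
    "global_fit",
    "parsimony_search",
    "select_components",
    "write_fit_report",
    "DEFAULT_BLOCKS",
]

# log10 bounds for dipolar constants (Hz^2) and correlation times (s)
_LOG_C_BOUNDS = (-6.0, 14.0)
_LOG_TAU_BOUNDS = (-12.0, -3.0)
_A_BOUNDS = (0.0, 1e7)

#: Parameter blocks tried, in order, by the parsimony search.  Intermediate
#: dynamics move first: temperature predominantly changes the confined-water
#: contribution, then the slow correlation time, then the dipolar constants.
DEFAULT_BLOCKS = (
    ("c_i_dd", "tau_i"),
    ("tau_s",),
    ("c_f_dd",),
    ("c_s_dd",),
    ("a",),
)

_AIC_TIE = 2.0  # |ΔAIC| below which the simpler model wins


class DegenerateComponentsWarning(UserWarning):
    """Two fitted correlation times collided; consider merging components."""


class RankDeficiencyWarning(UserWarning):
    """The fit Jacobian is rank deficient; parameters are under-determined."""


def _r1_curve(c_dd: np.ndarray, tau: np.ndarray, a: float,
              omega: np.ndarray) -> np.ndarray:
    wt = omega[None, :] * tau[:, None]
    bracket = tau[:, None] / (1.0 + wt * wt) + 4.0 * tau[:, None] / (1.0 + 4.0 * wt * wt)
    return c_dd @ bracket + a


# --------------------------------------------------------------------------
# Parameter packing for the canonical three-component model
# --------------------------------------------------------------------------

_LOG_PARAMS = {"c_s_dd", "c_i_dd", "c_f_dd", "tau_s", "tau_i", "tau_f"}
# component index (slow, intermediate, fast) per canonical name
_COMP_INDEX = {"c_s_dd": 0, "tau_s": 0, "c_i_dd": 1, "tau_i": 1,
               "c_f_dd": 2, "tau_f": 2}


class _Packer:
    """Maps a ConstraintMap over n profiles onto a flat optimization vector."""

    def __init__(self, constraints: ConstraintMap):
        self.constraints = constraints
        self.slot_index: dict = {}     # slot key -> position in x
        self.slot_names: list = []     # parallel: (representative name, is_log)
        self.assignment: list = []     # per profile: {name: ("slot", idx) | ("fixed", v)}
        for i in range(constraints.n_profiles):
            row = {}
            for name in PARAM_NAMES:
                con = constraints.constraint(i, name)
                if con.kind == "fixed":
                    row[name] = ("fixed", float(con.value))
                    continue
                key = (("shared", name, con.group) if con.kind == "shared"
                       else ("free", i, name))
                if key not in self.slot_index:
                    self.slot_index[key] = len(self.slot_names)
                    self.slot_names.append((name, name in _LOG_PARAMS))
                row[name] = ("slot", self.slot_index[key])
            self.assignment.append(row)

    @property
    def n_slots(self) -> int:
        return len(self.slot_names)

    def bounds(self) -> tuple:
        lo, hi = [], []
        for name, is_log in self.slot_names:
            if not is_log:
                b = _A_BOUNDS
            elif name.startswith("c_"):
                b = _LOG_C_BOUNDS
            else:
                b = _LOG_TAU_BOUNDS
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def pack(self, param_maps: Sequence[Mapping[str, float]]) -> np.ndarray:
        """Average natural-space parameter maps into an x0 vector."""
        acc = [[] for _ in range(self.n_slots)]
        for i, row in enumerate(self.assignment):
            for name, spec in row.items():
                if spec[0] == "slot":
                    value = float(param_maps[i][name])
                    _, is_log = self.slot_names[spec[1]]
                    acc[spec[1]].append(math.log10(max(value, 1e-30)) if is_log else value)
        return np.array([float(np.mean(v)) for v in acc])

    def unpack(self, x: np.ndarray) -> list:
        """x vector -> per-profile (c_dd[3], tau[3], a) arrays."""
        out = []
        for row in self.assignment:
            values = {}
            for name, spec in row.items():
                if spec[0] == "fixed":
                    values[name] = spec[1]
                else:
                    _, is_log = self.slot_names[spec[1]]
                    v = x[spec[1]]
                    values[name] = 10.0 ** v if is_log else v
            c = np.array([values["c_s_dd"], values["c_i_dd"], values["c_f_dd"]])
            tau = np.array([values["tau_s"], values["tau_i"], values["tau_f"]])
            out.append((c, tau, values["a"]))
        return out

    def slot_sigmas(self, x: np.ndarray, sigma_x: np.ndarray) -> list:
        """Per-profile {name: 1σ or None}; log-slot σ mapped to natural scale."""
        out = []
        for row in self.assignment:
            sig = {}
            for name, spec in row.items():
                if spec[0] == "fixed":
                    sig[name] = None
                else:
                    _, is_log = self.slot_names[spec[1]]
                    s = sigma_x[spec[1]]
                    if is_log:
                        sig[name] = 10.0 ** x[spec[1]] * math.log(10.0) * s
                    else:
                        sig[name] = s
            out.append(sig)
        return out


@dataclass
class GlobalFitResult:
    """Outcome of a (possibly multi-profile, constrained) dispersion fit."""

    models: list
    uncertainties: list
    statuses: list
    chisqr: float
    redchi: float
    aic: float
    n_free: int
    n_points: int
    success: bool
    message: str = ""
    seed: int | None = None
    constraints: ConstraintMap | None = None
    profile_keys: list = field(default_factory=list)

    @property
    def model(self) -> RelaxationModel:
        """The single fitted model (single-profile fits)."""
        if len(self.models) != 1:
            raise ValueError("result holds multiple profiles; index into .models")
        return self.models[0]


def _heuristic_params(profile: NMRDProfile, n_components: int = 3) -> dict:
    """Data-driven starting values: decade τ's, magnitude-matched C's."""
    mask = profile.uncensored
    y = profile.r1[mask]
    a0 = max(float(y.min()) * 0.9, 1e-3)
    r0 = max(float(y.max()) - a0, 1e-2)
    log_tau = np.linspace(-6.0, -8.0, n_components)
    tau = 10.0 ** log_tau
    c = r0 / (5.0 * tau * n_components)
    params = {"a": a0}
    if n_components == 3:
        for j, (cn, tn) in enumerate((("c_s_dd", "tau_s"), ("c_i_dd", "tau_i"),
                                      ("c_f_dd", "tau_f"))):
            params[cn] = c[j]
            params[tn] = tau[j]
    else:
        params["c"] = c
        params["tau"] = tau
    return params


def _result_metrics(chisq: float, n: int, p: int) -> tuple:
    redchi = chisq / max(n - p, 1)
    aic = n * math.log(max(chisq, 1e-300) / n) + 2.0 * p
    return redchi, aic


_PAIR_NAMES = (("c_s_dd", "tau_s"), ("c_i_dd", "tau_i"), ("c_f_dd", "tau_f"))


def _canonicalize(c: np.ndarray, tau: np.ndarray, a: float,
                  sigmas: Mapping[str, float | None]) -> tuple:
    """Sort fitted (C, τ) pairs by descending τ into the canonical slots.

    The three Lorentzian components are exchangeable; an optimizer may
    return them in any τ order.  When a permutation is needed, the
    per-pair uncertainties travel with their values.  Distinct τ are
    required; exact collisions are broken by C to keep the map total.
    """
    order = sorted(range(3), key=lambda j: (-tau[j], -c[j]))
    if list(order) != [0, 1, 2]:
        warnings.warn(
            "fitted correlation times came out of slow>intermediate>fast "
            "order; components were relabelled by rank",
            DegenerateComponentsWarning, stacklevel=3,
        )
    params, sig = {"a": a}, {"a": sigmas.get("a")}
    for slot, j in enumerate(order):
        cn, tn = _PAIR_NAMES[slot]
        cn_src, tn_src = _PAIR_NAMES[j]
        params[cn], params[tn] = c[j], tau[j]
        sig[cn], sig[tn] = sigmas.get(cn_src), sigmas.get(tn_src)
    return params, sig


def _check_degenerate(models: Iterable[RelaxationModel], ratio_tol: float = 2.0):
    for m in models:
        tau = m.tau
        for t1, t2 in zip(tau, tau[1:]):
            if t1 / t2 < ratio_tol:
                warnings.warn(
                    f"correlation times {t1:.3g} s and {t2:.3g} s are within a "
                    f"factor {ratio_tol:g}; consider merging the two components",
                    DegenerateComponentsWarning,
                    stacklevel=3,
                )


class GlobalDispersionFitter(BaseEstimator):
    """Weighted global fit of the three-component model over several profiles.

    Shared slots take one value across their group, fixed slots never move,
    free slots are independent per profile.

    Parameters
    ----------
    constraints : ConstraintMap or None
        Defaults to all-free for a single profile and fully-shared for
        several (the natural baseline of the parsimony strategy).
    n_starts : int
        Seeded multi-start count; the first start is unjittered.
    random_state : int or None
        Seed for the start jitter.
    init : RelaxationModel, sequence of RelaxationModel, or None
        Optional warm start(s), one per profile.

    Attributes (after ``fit``)
    --------------------------
    models_ : list of RelaxationModel
    result_ : GlobalFitResult
    """

    def __init__(self, constraints: ConstraintMap | None = None,
                 n_starts: int = 5, random_state: int | None = None,
                 init=None, max_nfev: int = 4000):
        self.constraints = constraints
        self.n_starts = n_starts
        self.random_state = random_state
        self.init = init
        self.max_nfev = max_nfev

    def fit(self, profiles, y=None):
        if isinstance(profiles, NMRDProfile):
            profiles = [profiles]
        profiles = list(profiles)
        if not profiles:
            raise ValueError("need at least one profile")
        constraints = self.constraints
        if constraints is None:
            constraints = (ConstraintMap.all_free(1) if len(profiles) == 1
                           else ConstraintMap.fully_shared(len(profiles)))
        if constraints.n_profiles != len(profiles):
            raise ValueError(
                f"constraint map covers {constraints.n_profiles} profiles, "
                f"got {len(profiles)}"
            )
        packer = _Packer(constraints)
        p = packer.n_slots

        data = []
        n_total = 0
        for prof in profiles:
            mask = prof.uncensored
            freqs = prof.freqs_hz[mask]
            y_obs = prof.r1[mask]
            sigma = (prof.r1_err[mask]
                     if prof.r1_err is not None and np.all(prof.r1_err[mask] > 0)
                     else y_obs)
            data.append((2.0 * np.pi * freqs, y_obs, sigma))
            n_total += y_obs.size
        min_needed = 0 if p == 0 else p + 1
        if n_total < max(min_needed, 8):
            raise InsufficientDataError(
                f"{n_total} uncensored points for {p} free parameters"
            )

        def residual(x):
            parts = []
            for (omega, y_obs, sigma), (c, tau, a) in zip(data, packer.unpack(x)):
                parts.append((_r1_curve(c, tau, a, omega) - y_obs) / sigma)
            return np.concatenate(parts)

        # evaluate-only mode when everything is fixed
        if p == 0:
            warnings.warn("all parameters fixed; evaluating without fitting",
                          UserWarning, stacklevel=2)
            resid = residual(np.empty(0))
            chisq = float(resid @ resid)
            redchi, aic = _result_metrics(chisq, n_total, 0)
            models = [
                RelaxationModel.from_params({
                    "c_s_dd": c[0], "tau_s": tau[0], "c_i_dd": c[1],
                    "tau_i": tau[1], "c_f_dd": c[2], "tau_f": tau[2], "a": a,
                })
                for c, tau, a in packer.unpack(np.empty(0))
            ]
            self.result_ = GlobalFitResult(
                models=models,
                uncertainties=[{n: None for n in PARAM_NAMES} for _ in models],
                statuses=[{n: constraints.status(i, n) for n in PARAM_NAMES}
                          for i in range(len(models))],
                chisqr=chisq, redchi=redchi, aic=aic, n_free=0,
                n_points=n_total, success=True, message="evaluate-only",
                seed=self.random_state, constraints=constraints,
                profile_keys=[prof.key() for prof in profiles],
            )
            self.models_ = models
            return self

        # starting point(s)
        if self.init is None:
            base_maps = [_heuristic_params(prof) for prof in profiles]
        else:
            init = self.init
            if isinstance(init, RelaxationModel):
                init = [init] * len(profiles)
            base_maps = [m.to_params() for m in init]
        x0 = packer.pack(base_maps)
        lo, hi = packer.bounds()
        x0 = np.clip(x0, lo, hi)

        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(max(self.n_starts, 1)):
            if start == 0:
                xs = x0
            else:
                jitter = np.array([
                    rng.normal(0.0, 0.3) if is_log else 0.0
                    for _, is_log in packer.slot_names
                ])
                scale = np.array([
                    1.0 if is_log else max(1.0 + 0.2 * rng.normal(), 0.05)
                    for _, is_log in packer.slot_names
                ])
                xs = np.clip(x0 * scale + jitter, lo, hi)
            try:
                res = optimize.least_squares(
                    residual, xs, bounds=(lo, hi), method="trf",
                    max_nfev=self.max_nfev, x_scale="jac",
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitConvergenceError("no multi-start converged")

        chisq = 2.0 * float(best.cost)
        redchi, aic = _result_metrics(chisq, n_total, p)

        # covariance in packed space, scaled by the residual variance
        jac = best.jac
        jtj = jac.T @ jac
        sv = np.linalg.svd(jtj, compute_uv=False)
        if sv[0] > 0 and sv[-1] / sv[0] < 1e-12:
            warnings.warn("fit is rank deficient; some parameters are "
                          "under-determined", RankDeficiencyWarning, stacklevel=2)
        s2 = chisq / max(n_total - p, 1)
        try:
            cov = np.linalg.pinv(jtj) * s2
            sigma_x = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            sigma_x = np.full(p, np.nan)

        models = []
        uncertainties = packer.slot_sigmas(best.x, sigma_x)
        for i, (c, tau, a) in enumerate(packer.unpack(best.x)):
            params, uncertainties[i] = _canonicalize(c, tau, a, uncertainties[i])
            models.append(RelaxationModel.from_params(params))
        _check_degenerate(models)
        statuses = [{n: constraints.status(i, n) for n in PARAM_NAMES}
                    for i in range(len(profiles))]
        self.result_ = GlobalFitResult(
            models=models, uncertainties=uncertainties, statuses=statuses,
            chisqr=chisq, redchi=redchi, aic=aic, n_free=p, n_points=n_total,
            success=True, message=best.message, seed=self.random_state,
            constraints=constraints,
            profile_keys=[prof.key() for prof in profiles],
        )
        self.models_ = models
        return self

    def predict(self, freqs_hz, profile_index: int = 0) -> np.ndarray:
        return evaluate_r1(self.models_[profile_index], freqs_hz)


class LorentzianDispersionFitter(BaseEstimator):
    """Fit one NMRD profile with 1–4 Lorentzian components plus an offset.

    Parameters
    ----------
    n_components : int
        Number of relaxation processes (1–4).
    fixed : mapping or None
        Canonical parameter name → value to clamp (three-component fits
        only), e.g. ``{"tau_s": 2.43e-6}``.
    n_starts, random_state, init, max_nfev
        As in :class:`GlobalDispersionFitter`.

    Attributes (after ``fit``)
    --------------------------
    model_ : RelaxationModel
    result_ : GlobalFitResult
    aic_, chisqr_, redchi_ : float
    """

    def __init__(self, n_components: int = 3, fixed: Mapping | None = None,
                 n_starts: int = 5, random_state: int | None = None,
                 init: RelaxationModel | None = None, max_nfev: int = 4000):
        self.n_components = n_components
        self.fixed = fixed
        self.n_starts = n_starts
        self.random_state = random_state
        self.init = init
        self.max_nfev = max_nfev

    def fit(self, X, y=None, r1_err=None, censored=None):
        if isinstance(X, NMRDProfile):
            profile = X
        else:
            profile = NMRDProfile("", float("nan"), np.asarray(X, float).ravel(),
                                  np.asarray(y, float), r1_err=r1_err,
                                  censored=censored)
        k = int(self.n_components)
        if not 1 <= k <= 4:
            raise ValueError("n_components must be in 1..4")
        if profile.n_uncensored < 2 * k + 2:
            raise InsufficientDataError(
                f"{profile.n_uncensored} uncensored points; "
                f"need >= {2 * k + 2} for {k} components"
            )
        if k == 3:
            result = self._fit_canonical(profile)
        else:
            if self.fixed:
                raise ValueError("fixed parameters are supported only for "
                                 "three-component fits")
            result = self._fit_generic(profile, k)
        self.result_ = result
        self.model_ = result.models[0]
        self.aic_ = result.aic
        self.chisqr_ = result.chisqr
        self.redchi_ = result.redchi
        return self

    def _fit_canonical(self, profile: NMRDProfile) -> GlobalFitResult:
        from .constraints import fixed as fixed_con
        entry = {}
        for name, value in (self.fixed or {}).items():
            if name not in PARAM_NAMES:
                raise KeyError(f"unknown parameter {name!r}")
            entry[name] = fixed_con(value)
        cmap = ConstraintMap([entry])
        fitter = GlobalDispersionFitter(
            constraints=cmap, n_starts=self.n_starts,
            random_state=self.random_state,
            init=self.init, max_nfev=self.max_nfev,
        )
        fitter.fit([profile])
        return fitter.result_

    def _fit_generic(self, profile: NMRDProfile, k: int) -> GlobalFitResult:
        mask = profile.uncensored
        omega = 2.0 * np.pi * profile.freqs_hz[mask]
        y = profile.r1[mask]
        sigma = (profile.r1_err[mask]
                 if profile.r1_err is not None and np.all(profile.r1_err[mask] > 0)
                 else y)
        n = y.size
        p = 2 * k + 1

        heur = _heuristic_params(profile, k)
        if self.init is not None:
            c0, tau0, a0 = self.init.c_dd, self.init.tau, self.init.offset_a
            if c0.size != k:
                raise ValueError("init model component count mismatch")
        else:
            c0, tau0, a0 = heur["c"], heur["tau"], heur["a"]
        x_base = np.concatenate([np.log10(np.maximum(c0, 1e-30)),
                                 np.log10(tau0), [a0]])
        lo = np.concatenate([np.full(k, _LOG_C_BOUNDS[0]),
                             np.full(k, _LOG_TAU_BOUNDS[0]), [_A_BOUNDS[0]]])
        hi = np.concatenate([np.full(k, _LOG_C_BOUNDS[1]),
                             np.full(k, _LOG_TAU_BOUNDS[1]), [_A_BOUNDS[1]]])
        x_base = np.clip(x_base, lo, hi)

        def residual(x):
            c = 10.0 ** x[:k]
            tau = 10.0 ** x[k:2 * k]
            return (_r1_curve(c, tau, x[2 * k], omega) - y) / sigma

        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(max(self.n_starts, 1)):
            xs = x_base if start == 0 else np.clip(
                x_base + np.concatenate([rng.normal(0, 0.3, 2 * k), [0.0]]), lo, hi)
            try:
                res = optimize.least_squares(residual, xs, bounds=(lo, hi),
                                             method="trf", max_nfev=self.max_nfev,
                                             x_scale="jac")
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitConvergenceError("no multi-start converged")

        chisq = 2.0 * float(best.cost)
        redchi, aic = _result_metrics(chisq, n, p)
        jtj = best.jac.T @ best.jac
        s2 = chisq / max(n - p, 1)
        sigma_x = np.sqrt(np.clip(np.diag(np.linalg.pinv(jtj)) * s2, 0.0, None))

        c = 10.0 ** best.x[:k]
        tau = 10.0 ** best.x[k:2 * k]
        a = best.x[2 * k]
        model = RelaxationModel.from_components(c, tau, a)
        _check_degenerate([model])
        order = np.argsort(tau)[::-1]
        unc = {}
        for rank, idx in enumerate(order):
            label = model.components[rank].label
            unc[f"c_dd[{label}]"] = c[idx] * math.log(10.0) * sigma_x[idx]
            unc[f"tau[{label}]"] = tau[idx] * math.log(10.0) * sigma_x[k + idx]
        unc["a"] = sigma_x[2 * k]
        return GlobalFitResult(
            models=[model], uncertainties=[unc],
            statuses=[{name: "free" for name in unc}],
            chisqr=chisq, redchi=redchi, aic=aic, n_free=p, n_points=n,
            success=True, message=best.message, seed=self.random_state,
            profile_keys=[profile.key()],
        )

    def predict(self, freqs_hz) -> np.ndarray:
        return evaluate_r1(self.model_, freqs_hz)


class ComponentSelector(BaseEstimator):
    """Choose the number of relaxation components by AIC.

    Fits k = 1..k_max models and selects the smallest k whose AIC is within
    2 units of the minimum (ties break toward parsimony).

    Attributes (after ``fit``)
    --------------------------
    k_ : int
    results_ : dict of {k: GlobalFitResult}
    aics_ : dict of {k: float}
    model_ : RelaxationModel of the selected fit
    """

    def __init__(self, k_max: int = 4, n_starts: int = 5,
                 random_state: int | None = None):
        self.k_max = k_max
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, profile: NMRDProfile, y=None):
        if not 1 <= self.k_max <= 4:
            raise ValueError("k_max must be in 1..4")
        results = {}
        for k in range(1, self.k_max + 1):
            try:
                fitter = LorentzianDispersionFitter(
                    n_components=k, n_starts=self.n_starts,
                    random_state=self.random_state,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DegenerateComponentsWarning)
                    warnings.simplefilter("ignore", RankDeficiencyWarning)
                    fitter.fit(profile)
                results[k] = fitter.result_
            except (FitConvergenceError, InsufficientDataError):
                continue
        if not results:
            raise FitConvergenceError("no component count produced a fit")
        aics = {k: r.aic for k, r in results.items()}
        best_aic = min(aics.values())
        self.k_ = min(k for k, a in aics.items() if a <= best_aic + _AIC_TIE)
        self.results_ = results
        self.aics_ = aics
        self.model_ = results[self.k_].models[0]
        return self

    def predict(self, freqs_hz) -> np.ndarray:
        return evaluate_r1(self.model_, freqs_hz)


@dataclass
class ParsimonyResult:
    constraints: ConstraintMap
    result: GlobalFitResult
    freed_blocks: list
    history: list  # (block, aic, accepted)


class ParsimonySearch(BaseEstimator):
    """Greedy minimal-difference analysis of a set of profiles.

    Starting from the fully-shared fit (one parameter set for all
    profiles), parameter blocks are freed in a fixed order — intermediate
    dynamics (C_i, τ_i) first, then τ_s, C_f, C_s, A — and a block is kept
    only when it improves the AIC by at least ``delta_aic``.  The outcome
    is the smallest set of per-profile parameters that explains the
    differences between the profiles.

    Attributes (after ``fit``)
    --------------------------
    constraints_ : ConstraintMap of the accepted minimal model
    result_ : GlobalFitResult of the final fit
    freed_blocks_ : list of accepted blocks
    history_ : list of (block, trial AIC, accepted) records
    """

    def __init__(self, delta_aic: float = 10.0, blocks=DEFAULT_BLOCKS,
                 n_starts: int = 5, random_state: int | None = None):
        self.delta_aic = delta_aic
        self.blocks = blocks
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, profiles, y=None, baseline: GlobalFitResult | None = None):
        profiles = list(profiles)
        if len(profiles) < 2:
            raise ValueError("parsimony search requires >= 2 profiles")
        cmap = ConstraintMap.fully_shared(len(profiles))
        if baseline is None:
            baseline = GlobalDispersionFitter(
                constraints=cmap, n_starts=self.n_starts,
                random_state=self.random_state,
            ).fit(profiles).result_
        current_map, current = cmap, baseline
        freed, history = [], []
        for block in self.blocks:
            trial_map = current_map.with_free_block(block)
            fitter = GlobalDispersionFitter(
                constraints=trial_map, n_starts=self.n_starts,
                random_state=self.random_state,
                init=current.models,  # warm start: χ² can only improve
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateComponentsWarning)
                warnings.simplefilter("ignore", RankDeficiencyWarning)
                trial = fitter.fit(profiles).result_
            accepted = trial.aic <= current.aic - self.delta_aic
            history.append((tuple(block), trial.aic, accepted))
            if accepted:
                current_map, current = trial_map, trial
                freed.append(tuple(block))
        self.constraints_ = current_map
        self.result_ = current
        self.freed_blocks_ = freed
        self.history_ = history
        return self


# --------------------------------------------------------------------------
# Functional wrappers
# --------------------------------------------------------------------------

def fit_single(profile: NMRDProfile, n_components: int = 3,
               init: RelaxationModel | None = None,
               fixed: Mapping | None = None, n_starts: int = 5,
               seed: int | None = None) -> GlobalFitResult:
    """Weighted multi-start fit of one profile; see LorentzianDispersionFitter."""
    fitter = LorentzianDispersionFitter(
        n_components=n_components, fixed=fixed, n_starts=n_starts,
        random_state=seed, init=init,
    )
    return fitter.fit(profile).result_


def global_fit(profiles, constraints: ConstraintMap | None = None,
               init=None, n_starts: int = 5,
               seed: int | None = None) -> GlobalFitResult:
    """Constrained fit over several profiles; see GlobalDispersionFitter."""
    fitter = GlobalDispersionFitter(constraints=constraints, n_starts=n_starts,
                                    random_state=seed, init=init)
    return fitter.fit(profiles).result_


def parsimony_search(profiles, baseline: GlobalFitResult | None = None,
                     delta_aic: float = 10.0, n_starts: int = 5,
                     seed: int | None = None) -> ParsimonyResult:
    """Greedy minimal-parameter comparison of profiles; see ParsimonySearch."""
    search = ParsimonySearch(delta_aic=delta_aic, n_starts=n_starts,
                             random_state=seed)
    search.fit(profiles, baseline=baseline)
    return ParsimonyResult(search.constraints_, search.result_,
                           search.freed_blocks_, search.history_)


def select_components(profile: NMRDProfile, k_max: int = 4, n_starts: int = 5,
                      seed: int | None = None) -> tuple:
    """AIC selection of the component count; returns ``(k, {k: result})``."""
    selector = ComponentSelector(k_max=k_max, n_starts=n_starts,
                                 random_state=seed)
    selector.fit(profile)
    return selector.k_, selector.results_


def write_fit_report(results: Sequence[GlobalFitResult], path) -> pd.DataFrame:
    """Tabulate fits in the layout of a published parameter table.

    One row per profile: sample, temperature, each canonical parameter with
    its 1σ uncertainty and its free/fixed/shared status, then the
    goodness-of-fit block.  Written as CSV; the frame is also returned.
    """
    rows = []
    for result in results:
        for i, model in enumerate(result.models):
            sample_id, temp = (result.profile_keys[i]
                               if result.profile_keys else ("", float("nan")))
            row = {"sample_id": sample_id, "temperature_k": temp}
            params = model.to_params()
            unc = result.uncertainties[i]
            status = result.statuses[i]
            for name in PARAM_NAMES:
                row[name] = params[name]
                row[f"{name}_unc"] = unc.get(name)
                row[f"{name}_status"] = status.get(name, "free")
            row.update(chisqr=result.chisqr, redchi=result.redchi,
                       aic=result.aic, n_free=result.n_free,
                       n_points=result.n_points)
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
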