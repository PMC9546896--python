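"""Closed-form relaxation-decay models and their analytic Jacobians.

Three signal models for spin-lock (T1ρ) relaxometry of cartilage-like
tissue, all functions of the spin-lock time ``t`` (milliseconds):

* mono-exponential:      ``s(t) = A · exp(−t/T1ρ)``
* bi-exponential:        ``s(t) = A · [f·exp(−t/T1ρs) + (1−f)·exp(−t/T1ρl)]``
* stretched-exponential: ``s(t) = A · exp(−(t/T1ρ*)^β)``,  ``0 < β ≤ 1``

The bi-exponential model describes two water compartments (short fraction
``f`` relaxing with ``T1ρs``, the rest with ``T1ρl``); the stretched
exponential models a continuous distribution of relaxation times whose
breadth is controlled by the stretching exponent β (β = 1 is
mono-exponential).

The amplitude ``A`` may be complex (MRI signals are), but the Jacobians
treat it as a single real degree of freedom: fitting phase-aligns the data
first, and the amplitude carries zero weight in schedule optimization.

All times are in milliseconds throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, DomainError

__all__ = [
    "BiExpParams",
    "StretchedParams",
    "MonoExpParams",
    "ParamBox",
    "MODEL_PARAM_NAMES",
    "default_box",
    "signal_biexp",
    "signal_stretched",
    "signal_mono",
    "jacobian_biexp",
    "jacobian_stretched",
    "jacobian_mono",
    "signal_array",
    "jacobian_array",
]

#: Parameter ordering per model; index 0 is always the amplitude.
MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "mono": ("amplitude", "t1rho"),
    "bi": ("amplitude", "fraction", "t1rho_short", "t1rho_long"),
    "stretched": ("amplitude", "t1rho_star", "beta"),
}

# Expected parameter ranges in healthy/degraded knee cartilage (ms for times).
_DEFAULT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "mono": {"amplitude": (0.0, 1e10), "t1rho": (1.0, 90.0)},
    "bi": {
        "amplitude": (0.0, 1e10),
        "fraction": (0.05, 0.95),
        "t1rho_short": (1.0, 10.0),
        "t1rho_long": (30.0, 90.0),
    },
    "stretched": {
        "amplitude": (0.0, 1e10),
        "t1rho_star": (10.0, 90.0),
        "beta": (0.4, 1.0),
    },
}


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise DomainError("spin-lock times must be finite and non-negative")
    return t


@dataclass(frozen=True)
class BiExpParams:
    """Point in bi-exponential parameter space: (A, f, T1ρs, T1ρl)."""

    amplitude: complex
    fraction: float
    t1rho_short: float
    t1rho_long: float

    def __post_init__(self):
        if not (0.0 < self.fraction < 1.0):
            raise DomainError(f"fraction must lie in (0, 1), got {self.fraction}")
        if self.t1rho_short <= 0 or self.t1rho_long <= 0:
            raise DomainError("relaxation times must be positive")

    def as_array(self) -> np.ndarray:
        a = self.amplitude
        dtype = complex if np.iscomplexobj(np.asarray(a)) and np.imag(a) != 0 else float
        return np.array(
            [a if dtype is complex else np.real(a), self.fraction, self.t1rho_short, self.t1rho_long],
            dtype=dtype,
        )


@dataclass(frozen=True)
class StretchedParams:
    """Point in stretched-exponential parameter space: (A, T1ρ*, β)."""

    amplitude: complex
    t1rho_star: float
    beta: float

    def __post_init__(self):
        if self.t1rho_star <= 0:
            raise DomainError("t1rho_star must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise DomainError(f"beta must lie in (0, 1], got {self.beta}")

    def as_array(self) -> np.ndarray:
        a = self.amplitude
        dtype = complex if np.iscomplexobj(np.asarray(a)) and np.imag(a) != 0 else float
        return np.array(
            [a if dtype is complex else np.real(a), self.t1rho_star, self.beta], dtype=dtype
        )


@dataclass(frozen=True)
class MonoExpParams:
    """Point in mono-exponential parameter space: (A, T1ρ)."""

    amplitude: complex
    t1rho: float

    def __post_init__(self):
        if self.t1rho <= 0:
            raise DomainError("t1rho must be positive")

    def as_array(self) -> np.ndarray:
        a = self.amplitude
        dtype = complex if np.iscomplexobj(np.asarray(a)) and np.imag(a) != 0 else float
        return np.array([a if dtype is complex else np.real(a), self.t1rho], dtype=dtype)


_PARAM_CLASSES = {"mono": MonoExpParams, "bi": BiExpParams, "stretched": StretchedParams}


@dataclass(frozen=True)
class ParamBox:
    """Axis-aligned box of admissible parameter values for one model.

    The fit is constrained to this box; schedule optimization samples
    parameters uniformly from it. Defaults represent the expected range of
    values in knee cartilage (see :func:`default_box`).
    """

    model: str
    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if len(self.names) != lower.size or lower.size != upper.size:
            raise ConfigError("box bounds must match the parameter names in length")
        if np.any(lower >= upper):
            bad = [n for n, lo, hi in zip(self.names, lower, upper) if lo >= hi]
            raise ConfigError(f"box min must be < max for every parameter; violated by {bad}")

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta, atol: float = 0.0) -> bool:
        theta = np.real(np.asarray(theta, dtype=complex))
        return bool(np.all(theta >= self.lower - atol) and np.all(theta <= self.upper + atol))

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)

    def replace_bounds(self, **bounds: tuple[float, float]) -> "ParamBox":
        lower, upper = self.lower.copy(), self.upper.copy()
        for name, (lo, hi) in bounds.items():
            if name not in self.names:
                raise ConfigError(f"unknown parameter {name!r} for model {self.model!r}")
            i = self.names.index(name)
            lower[i], upper[i] = lo, hi
        return ParamBox(self.model, self.names, lower, upper)


def default_box(model: str) -> ParamBox:
    """Default constraint box for ``model`` ('mono' | 'bi' | 'stretched')."""
    if model not in _DEFAULT_BOUNDS:
        raise ConfigError(f"unknown model {model!r}; expected one of {sorted(_DEFAULT_BOUNDS)}")
    names = MODEL_PARAM_NAMES[model]
    b = _DEFAULT_BOUNDS[model]
    return ParamBox(
        model,
        names,
        np.array([b[n][0] for n in names]),
        np.array([b[n][1] for n in names]),
    )


# ---------------------------------------------------------------------------
# scalar (typed) API
# ---------------------------------------------------------------------------

def signal_biexp(t, params: BiExpParams):
    """Noiseless bi-exponential signal ``A·[f·e^{−t/T1ρs} + (1−f)·e^{−t/T1ρl}]``."""
    t = _check_t(t)
    decay = params.fraction * np.exp(-t / params.t1rho_short) + (
        1.0 - params.fraction
    ) * np.exp(-t / params.t1rho_long)
    out = np.asarray(params.amplitude * decay)
    return out[()] if out.ndim == 0 else out


def signal_stretched(t, params: StretchedParams):
    """Noiseless stretched-exponential signal ``A·exp(−(t/T1ρ*)^β)``.

    ``t = 0`` is handled as the limit (→ A) to avoid ``0^β`` for β < 1.
    """
    t = _check_t(t)
    with np.errstate(divide="ignore"):
        u = t / params.t1rho_star
        decay = np.where(t > 0, np.exp(-(u ** params.beta)), 1.0)
    out = np.asarray(params.amplitude * decay)
    return out[()] if out.ndim == 0 else out


def signal_mono(t, params: MonoExpParams):
    """Noiseless mono-exponential signal ``A·exp(−t/T1ρ)``."""
    t = _check_t(t)
    out = np.asarray(params.amplitude * np.exp(-t / params.t1rho))
    return out[()] if out.ndim == 0 else out


def jacobian_biexp(t, params: BiExpParams) -> np.ndarray:
    """Row(s) of partial derivatives of the bi-exponential signal.

    Columns are ∂s/∂[A, f, T1ρs, T1ρl]; shape ``(4,)`` for scalar ``t``,
    else ``t.shape + (4,)``. A is treated as real (phase-aligned data).
    """
    t = _check_t(t)
    if params.t1rho_short == 0 or params.t1rho_long == 0:
        raise DomainError("relaxation times must be nonzero")
    a = np.real(params.amplitude)
    f, ts, tl = params.fraction, params.t1rho_short, params.t1rho_long
    es, el = np.exp(-t / ts), np.exp(-t / tl)
    rows = np.stack(
        [
            f * es + (1.0 - f) * el,
            a * (es - el),
            a * f * t / ts**2 * es,
            a * (1.0 - f) * t / tl**2 * el,
        ],
        axis=-1,
    )
    return rows


def jacobian_stretched(t, params: StretchedParams) -> np.ndarray:
    """Row(s) of partial derivatives of the stretched-exponential signal.

    Columns are ∂s/∂[A, T1ρ*, β]; the ``t = 0`` row is the limit
    ``[1, 0, 0]`` (the β-derivative contains ``log(t/T1ρ*)``).
    """
    t = _check_t(t)
    a = np.real(params.amplitude)
    tstar, beta = params.t1rho_star, params.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        u = t / tstar
        ub = np.where(t > 0, u**beta, 0.0)
        e = np.exp(-ub)
        logu = np.where(t > 0, np.log(np.where(t > 0, u, 1.0)), 0.0)
        rows = np.stack(
            [
                np.where(t > 0, e, 1.0),
                a * beta * e * ub / tstar,
                -a * e * ub * logu,
            ],
            axis=-1,
        )
    return rows


def jacobian_mono(t, params: MonoExpParams) -> np.ndarray:
    """Row(s) of partial derivatives of the mono-exponential signal w.r.t. [A, T1ρ]."""
    t = _check_t(t)
    a = np.real(params.amplitude)
    e = np.exp(-t / params.t1rho)
    return np.stack([e, a * t / params.t1rho**2 * e], axis=-1)


# ---------------------------------------------------------------------------
# batched (array) API — the workhorse for optimization and Monte Carlo
# ---------------------------------------------------------------------------

def signal_array(model: str, t: Sequence[float], theta: np.ndarray) -> np.ndarray:
    """Vectorized noiseless signal.

    Parameters
    ----------
    model : 'mono' | 'bi' | 'stretched'
    t : (K,) spin-lock times, ms
    theta : (..., P) parameter array in the model's canonical order

    Returns
    -------
    (..., K) signal array (real if ``theta`` is real).
    """
    t = _check_t(np.atleast_1d(t))
    theta = np.asarray(theta)
    a = theta[..., 0:1]
    if model == "mono":
        return a * np.exp(-t / theta[..., 1:2])
    if model == "bi":
        f = theta[..., 1:2]
        return a * (
            f * np.exp(-t / theta[..., 2:3]) + (1.0 - f) * np.exp(-t / theta[..., 3:4])
        )
    if model == "stretched":
        with np.errstate(divide="ignore"):
            u = t / theta[..., 1:2]
            ub = np.where(t > 0, u, 1.0) ** theta[..., 2:3]
            return a * np.where(t > 0, np.exp(-ub), 1.0)
    raise ConfigError(f"unknown model {model!r}")


def jacobian_array(model: str, t: Sequence[float], theta: np.ndarray) -> np.ndarray:
    """Vectorized Jacobian, shape ``theta.shape[:-1] + (K, P)``.

    The amplitude is treated as real; ``theta`` must be real-valued.
    """
    t = _check_t(np.atleast_1d(t))
    theta = np.asarray(theta, dtype=float)
    a = theta[..., 0:1]
    if model == "mono":
        T = theta[..., 1:2]
        e = np.exp(-t / T)
        return np.stack([e, a * t / T**2 * e], axis=-1)
    if model == "bi":
        f, ts, tl = theta[..., 1:2], theta[..., 2:3], theta[..., 3:4]
        es, el = np.exp(-t / ts), np.exp(-t / tl)
        return np.stack(
            [f * es + (1 - f) * el, a * (es - el), a * f * t / ts**2 * es,
             a * (1 - f) * t / tl**2 * el],
            axis=-1,
        )
    if model == "stretched":
        tstar, beta = theta[..., 1:2], theta[..., 2:3]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = t / tstar
            pos = t > 0
            ub = np.where(pos, u, 1.0) ** beta * pos
            e = np.where(pos, np.exp(-ub), 1.0)
            logu = np.where(pos, np.log(np.where(pos, u, 1.0)), 0.0)
        return np.stack(
            [e, a * beta * e * ub / tstar, -a * e * ub * logu], axis=-1
        )
    raise ConfigError(f"unknown model {model!r}")


def params_from_array(model: str, theta) -> "BiExpParams | StretchedParams | MonoExpParams":
    """Build the typed parameter object for ``model`` from a flat array."""
    cls = _PARAM_CLASSES[model]
    vals = list(np.asarray(theta))
    return cls(vals[0], *[float(np.real(v)) for v in vals[1:]])
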