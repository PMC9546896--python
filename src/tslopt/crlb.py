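"""Fisher information and Cramér–Rao schedule-scoring criteria.

A spin-lock-time schedule ``t = [t_1 … t_K]`` is scored by how tightly it
constrains the model parameters: the Fisher Information Matrix (FIM)

    I(t, θ) = (1/σ²) Σ_k J(t_k, θ)ᵀ J(t_k, θ)

is inverted to the Cramér–Rao matrix ``V = I⁻¹`` whose diagonal holds the
CRLBs — the minimal variances of any unbiased estimator. Because the bound
depends on the (unknown) tissue parameters, both criteria average over a
set of parameter draws ``θ_s`` taken uniformly from the constraint box:

* CRLB cost:   mean_s  Σ_i w_i · V(t, θ_s)_{ii}
* MCRLB cost:  mean_s  Σ_i w_i · sqrt(|V(t, θ_s)_{ii}|) / |θ_s,i|

The modified criterion (MCRLB) targets equal *relative* precision across
parameters and keeps large absolute bounds (long relaxation times) from
dominating the score. The amplitude weight is zero in both defaults: the
amplitude is easy to estimate and its bound is not of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, EvaluationError
from .models import MODEL_PARAM_NAMES, ParamBox, jacobian_array

__all__ = [
    "FisherMatrix",
    "CRMatrix",
    "ParamSampleSet",
    "default_weights",
    "sample_params",
    "fim",
    "crm",
    "crlb_cost",
    "mcrlb_cost",
    "ScheduleCost",
]

#: Default per-parameter weights for the scoring criteria, per model.
#: Chosen to equalize the normalized bounds across parameters.
DEFAULT_WEIGHTS: dict[str, tuple[float, ...]] = {
    "bi": (0.0, 0.3, 0.4, 0.3),
    "stretched": (0.0, 0.9, 0.1),
    "mono": (0.0, 1.0),
}

#: FIMs whose condition-number estimate exceeds this are treated as degenerate.
DEFAULT_CONDITION_LIMIT = 1e12


def default_weights(model: str) -> np.ndarray:
    if model not in DEFAULT_WEIGHTS:
        raise ConfigError(f"no default weights for model {model!r}")
    return np.asarray(DEFAULT_WEIGHTS[model], dtype=float)


def _tsl_array(schedule) -> np.ndarray:
    """Accept a Schedule object or any sequence of spin-lock times."""
    tsl = getattr(schedule, "tsl_ms", schedule)
    tsl = np.asarray(tsl, dtype=float).ravel()
    if tsl.size == 0:
        raise ConfigError("schedule must contain at least one spin-lock time")
    return tsl


def _theta_array(params, model: str | None = None) -> tuple[np.ndarray, str]:
    if hasattr(params, "as_array"):
        cls = type(params).__name__
        model = {"MonoExpParams": "mono", "BiExpParams": "bi", "StretchedParams": "stretched"}[cls]
        return np.real(params.as_array()).astype(float), model
    if model is None:
        raise ConfigError("model name required when params is a plain array")
    return np.asarray(params, dtype=float), model


@dataclass(frozen=True)
class FisherMatrix:
    """Fisher information for one (schedule, θ) pair at noise level ``sigma``."""

    matrix: np.ndarray
    sigma: float

    @property
    def n_params(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CRMatrix:
    """Cramér–Rao matrix (inverse FIM); ``degenerate`` marks an unreliable inverse."""

    matrix: np.ndarray
    condition_number: float
    degenerate: bool

    @property
    def crlbs(self) -> np.ndarray:
        """Per-parameter lower variance bounds (the diagonal)."""
        return np.diagonal(self.matrix)


@dataclass(frozen=True)
class ParamSampleSet:
    """Uniform parameter draws from a box, with provenance for reproducibility."""

    model: str
    theta: np.ndarray  # (S, P)
    box: ParamBox
    seed: int

    @property
    def count(self) -> int:
        return self.theta.shape[0]


def sample_params(box: ParamBox, count: int, seed: int = 0) -> ParamSampleSet:
    """Draw ``count`` i.i.d. uniform parameter vectors from ``box``.

    The amplitude (index 0) is fixed at 1: signals are normalized before
    fitting and the amplitude carries zero weight in the criteria, so unit
    amplitude is the consistent reference scale.
    """
    if count < 1:
        raise ConfigError("count must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(box.lower, box.upper, size=(count, box.n_params))
    theta[:, 0] = 1.0
    return ParamSampleSet(model=box.model, theta=theta, box=box, seed=seed)


def fim(schedule, params, sigma: float = 1.0, model: str | None = None) -> FisherMatrix:
    """Fisher Information Matrix ``(1/σ²) Σ_k J(t_k,θ)ᵀ J(t_k,θ)``."""
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    tsl = _tsl_array(schedule)
    theta, model = _theta_array(params, model)
    J = jacobian_array(model, tsl, theta)  # (K, P)
    return FisherMatrix(matrix=(J.T @ J) / sigma**2, sigma=sigma)


def crm(
    info: FisherMatrix | np.ndarray,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> CRMatrix:
    """Invert a FIM into the Cramér–Rao matrix, flagging ill-conditioned cases.

    When the condition number exceeds ``condition_limit`` (or the matrix is
    singular) the result is flagged ``degenerate``; the caller decides
    whether to skip the sample or assign an infinite cost.
    """
    mat = info.matrix if isinstance(info, FisherMatrix) else np.asarray(info, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigError("FIM must be square")
    try:
        cond = np.linalg.cond(mat)
    except np.linalg.LinAlgError:  # pragma: no cover - cond rarely raises
        cond = np.inf
    if not np.isfinite(cond) or cond > condition_limit:
        return CRMatrix(matrix=np.full_like(mat, np.nan), condition_number=float(cond), degenerate=True)
    return CRMatrix(matrix=np.linalg.inv(mat), condition_number=float(cond), degenerate=False)


def _check_weights(weights, n_params: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != n_params:
        raise ConfigError(f"weights length {w.size} != number of parameters {n_params}")
    if np.any(w < 0):
        raise ConfigError("weights must be non-negative")
    return w


def _averaged_cost(
    schedule,
    samples: ParamSampleSet,
    weights,
    sigma: float,
    condition_limit: float,
    modified: bool,
) -> float:
    tsl = _tsl_array(schedule)
    w = _check_weights(weights, samples.theta.shape[1])
    total, n_used = 0.0, 0
    for theta in samples.theta:
        V = crm(fim(tsl, theta, sigma=sigma, model=samples.model), condition_limit)
        if V.degenerate:
            continue
        diag = V.crlbs
        if modified:
            denom = np.abs(theta)
            if np.any((w > 0) & (denom == 0)):
                warnings.warn("sample with zero weighted parameter skipped (cannot normalize)")
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(w > 0, np.sqrt(np.abs(diag)) / np.where(denom > 0, denom, 1.0), 0.0)
            total += float(w @ contrib)
        else:
            total += float(w @ diag)
        n_used += 1
    if n_used == 0:
        raise EvaluationError("every parameter sample was degenerate for this schedule")
    if n_used < samples.count:
        warnings.warn(
            f"{samples.count - n_used}/{samples.count} degenerate parameter samples skipped; "
            "cost renormalized by the surviving count"
        )
    return total / n_used


def crlb_cost(
    schedule,
    samples: ParamSampleSet,
    weights=None,
    sigma: float = 1.0,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> float:
    """Weighted CRLB averaged over the parameter draws (lower is better)."""
    w = default_weights(samples.model) if weights is None else weights
    return _averaged_cost(schedule, samples, w, sigma, condition_limit, modified=False)


def mcrlb_cost(
    schedule,
    samples: ParamSampleSet,
    weights=None,
    sigma: float = 1.0,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> float:
    """Modified CRLB: weighted relative root-bounds averaged over the draws.

    Normalizing each root-CRLB by |θ_i| targets equal relative precision
    across parameters and keeps large absolute bounds from dominating.
    """
    w = default_weights(samples.model) if weights is None else weights
    return _averaged_cost(schedule, samples, w, sigma, condition_limit, modified=True)


class ScheduleCost:
    """Fast batched schedule-scoring over a fixed TSL grid.

    Precomputes the per-grid-node information contributions
    ``G[s, j] = J(τ_j, θ_s)ᵀ J(τ_j, θ_s) / σ²`` for every parameter draw so
    that the FIM of any schedule (a multiset of grid nodes) is a sum of
    precomputed P×P blocks. Used by the exhaustive and POSS optimizers;
    agrees with :func:`crlb_cost` / :func:`mcrlb_cost` to round-off.

    Ill-conditioned samples (condition estimate ``‖F‖₁·‖F⁻¹‖₁`` above
    ``condition_limit``, or singular) are skipped and the average is taken
    over the survivors; a schedule with no surviving sample scores +inf.
    """

    def __init__(
        self,
        model: str,
        grid,
        samples: ParamSampleSet,
        weights=None,
        criterion: str = "crlb",
        sigma: float = 1.0,
        condition_limit: float = DEFAULT_CONDITION_LIMIT,
    ):
        if criterion not in ("crlb", "mcrlb"):
            raise ConfigError(f"criterion must be 'crlb' or 'mcrlb', got {criterion!r}")
        if samples.model != model:
            raise ConfigError(f"sample set is for model {samples.model!r}, not {model!r}")
        self.model = model
        self.criterion = criterion
        self.sigma = float(sigma)
        self.condition_limit = float(condition_limit)
        self.nodes = np.asarray(getattr(grid, "values", grid), dtype=float).ravel()
        self.samples = samples
        self.weights = (
            default_weights(model) if weights is None else _check_weights(weights, samples.theta.shape[1])
        )
        J = jacobian_array(model, self.nodes, samples.theta)  # (S, n, P)
        self._G = np.einsum("snp,snq->snpq", J, J) / self.sigma**2  # (S, n, P, P)
        self._abs_theta = np.abs(samples.theta)  # (S, P)

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def indices_of(self, tsl_ms) -> np.ndarray:
        """Map spin-lock times onto grid-node indices (must be grid members)."""
        tsl = _tsl_array(tsl_ms)
        idx = np.searchsorted(self.nodes, tsl)
        idx = np.clip(idx, 0, self.n_nodes - 1)
        left = np.clip(idx - 1, 0, self.n_nodes - 1)
        idx = np.where(
            np.abs(self.nodes[left] - tsl) < np.abs(self.nodes[idx] - tsl), left, idx
        )
        if not np.allclose(self.nodes[idx], tsl, atol=1e-9):
            off = tsl[~np.isclose(self.nodes[idx], tsl, atol=1e-9)]
            raise ConfigError(f"spin-lock times {off} are not grid members")
        return idx

    def __call__(self, schedule) -> float:
        return float(self.evaluate_index_sets(self.indices_of(schedule)[None, :])[0])

    def cost_of_counts(self, counts: np.ndarray) -> float:
        """Cost of a schedule given per-node multiplicities."""
        counts = np.asarray(counts)
        idx = np.repeat(np.arange(self.n_nodes), counts)
        if idx.size == 0:
            return np.inf
        return float(self.evaluate_index_sets(idx[None, :])[0])

    def evaluate_index_sets(self, idx: np.ndarray) -> np.ndarray:
        """Scores for ``M`` schedules given as an ``(M, K)`` array of node indices.

        Loops over parameter samples and batches the M matrix inversions per
        sample, which keeps peak memory at O(M·P²).
        """
        idx = np.asarray(idx, dtype=np.intp)
        if idx.ndim != 2:
            raise ConfigError("idx must be (M, K)")
        M = idx.shape[0]
        P = self.samples.theta.shape[1]
        w = self.weights
        total = np.zeros(M)
        n_used = np.zeros(M, dtype=np.intp)
        eye_norm = np.finfo(float).tiny
        for s in range(self.samples.count):
            G = self._G[s]
            F = np.zeros((M, P, P))
            for k in range(idx.shape[1]):
                F += G[idx[:, k]]
            det = np.linalg.det(F)
            good = np.isfinite(det) & (np.abs(det) > eye_norm)
            if not np.any(good):
                continue
            Fg = F[good]
            with np.errstate(over="ignore", invalid="ignore"):
                Vg = np.linalg.inv(Fg)
            # 1-norm condition estimate; cheap once the inverse is in hand
            cond = np.abs(Fg).sum(axis=-2).max(axis=-1) * np.abs(Vg).sum(axis=-2).max(axis=-1)
            ok = np.isfinite(cond) & (cond <= self.condition_limit)
            diag = np.diagonal(Vg, axis1=-2, axis2=-1)  # (G, P)
            if self.criterion == "crlb":
                contrib = diag @ w
            else:
                denom = self._abs_theta[s]
                safe = np.where(denom > 0, denom, 1.0)
                contrib = (np.sqrt(np.abs(diag)) / safe) @ w
            good_idx = np.flatnonzero(good)[ok]
            total[good_idx] += contrib[ok]
            n_used[good_idx] += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(n_used > 0, total / np.maximum(n_used, 1), np.inf)
        return out
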