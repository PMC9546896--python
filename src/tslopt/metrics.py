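"""Error metrics, goodness-of-fit, and AICc model selection.

MNAE (mean normalized absolute error) is the workhorse comparison metric:
mean over an ROI of |θ − θ̂|/|θ| per parameter, combined across parameters
as a weighted average with the same weights used in schedule optimization.

Model selection uses the small-sample corrected Akaike criterion

    AICc = 2P + K·ln(SSE/K) + 2P(P+1)/(K − P − 1)

assuming i.i.d. Gaussian residuals around the fitted curve; the model with
the lowest AICc fits best after the complexity penalty.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ConfigError, DomainError
from .models import MODEL_PARAM_NAMES, ParamBox

__all__ = [
    "mnae",
    "combined_nae",
    "combined_nae_map",
    "r_squared",
    "aicc",
    "select_model",
    "classification_percentages",
]


def _as_param_stack(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim < 1:
        raise ConfigError("expected an array with a trailing parameter axis")
    return a


def mnae(estimates, references, roi_mask=None) -> np.ndarray:
    """Per-parameter mean normalized absolute error over an ROI.

    ``estimates`` and ``references`` share a shape ``(..., P)``; ``roi_mask``
    selects voxels along the leading axes (all voxels when omitted). Voxels
    with a zero reference value are excluded per parameter, with a warning.
    """
    est = _as_param_stack(estimates)
    ref = _as_param_stack(references)
    if est.shape != ref.shape:
        raise ConfigError(f"shape mismatch: estimates {est.shape} vs references {ref.shape}")
    if roi_mask is not None:
        est = est[np.asarray(roi_mask, dtype=bool)]
        ref = ref[np.asarray(roi_mask, dtype=bool)]
    est = est.reshape(-1, est.shape[-1])
    ref = ref.reshape(-1, ref.shape[-1])
    if est.shape[0] == 0:
        raise ConfigError("empty ROI")
    nonzero = ref != 0
    if not np.all(nonzero):
        warnings.warn(
            f"{int((~nonzero).sum())} voxel/parameter entries with zero reference excluded from MNAE"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        nae = np.where(nonzero, np.abs(ref - est) / np.abs(np.where(nonzero, ref, 1.0)), np.nan)
    counts = nonzero.sum(axis=0)
    if np.any(counts == 0):
        raise DomainError("a parameter has zero reference everywhere in the ROI")
    return np.nansum(nae, axis=0) / counts


def combined_nae(per_param_nae, weights) -> float:
    """Weighted average of per-parameter MNAEs: Σ w_i·MNAE_i / Σ w_i."""
    nae = np.asarray(per_param_nae, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if nae.size != w.size:
        raise ConfigError("weights length must match the number of parameters")
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigError("weights must be non-negative with a positive sum")
    return float((w @ nae) / w.sum())


def combined_nae_map(nae_maps: np.ndarray, weights) -> np.ndarray:
    """Voxelwise combined NAE: collapse the trailing parameter axis."""
    maps = _as_param_stack(nae_maps)
    w = np.asarray(weights, dtype=float).ravel()
    if maps.shape[-1] != w.size:
        raise ConfigError("weights length must match the parameter axis")
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigError("weights must be non-negative with a positive sum")
    return maps @ (w / w.sum())


def r_squared(estimates, references, conventional: bool = False) -> float:
    """Deviation-ratio goodness metric between estimates and references.

    Default form: Σ(θ̂_s − θ̄)² / Σ(θ_s − θ̄)² with θ̄ the reference mean —
    the ratio of explained to reference deviation. ``conventional=True``
    gives the textbook coefficient of determination 1 − SSE/SST instead.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    ref = np.asarray(references, dtype=float).ravel()
    if est.shape != ref.shape:
        raise ConfigError("estimates and references must have the same length")
    mean = ref.mean()
    sst = np.sum((ref - mean) ** 2)
    if sst == 0:
        raise DomainError("references are constant; R² undefined")
    if conventional:
        return float(1.0 - np.sum((ref - est) ** 2) / sst)
    return float(np.sum((est - mean) ** 2) / sst)


def aicc(sse: float, k_samples: int, p_params: int) -> float:
    """Corrected Akaike Information Criterion (natural log).

    Requires K > P + 1 (otherwise the small-sample correction diverges) and
    SSE > 0.
    """
    if k_samples <= p_params + 1:
        raise DomainError(f"AICc undefined for K={k_samples} <= P+1={p_params + 1}")
    if sse <= 0:
        raise DomainError("AICc requires SSE > 0")
    return float(
        2 * p_params
        + k_samples * np.log(sse / k_samples)
        + 2 * p_params * (p_params + 1) / (k_samples - p_params - 1)
    )


#: Named-parameter count per model used in the AICc penalty (the complex
#: amplitude counts once).
MODEL_P = {name: len(params) for name, params in MODEL_PARAM_NAMES.items()}

_AICC_TIE_TOL = 1e-9


def select_model(
    curve,
    boxes: dict[str, ParamBox] | None = None,
    models: tuple[str, ...] = ("mono", "bi", "stretched"),
    n_starts: int = 5,
) -> tuple[str, dict[str, float]]:
    """Fit all candidate models to one curve and pick the lowest AICc.

    Ties within 1e−9 (e.g. a stretched fit pinned at β = 1 duplicating the
    mono-exponential) resolve to the model with fewer parameters. A fit
    failure labels the curve ``"unclassified"``.
    """
    from .fitting import fit_nls  # local import to avoid a cycle

    boxes = boxes or {}
    scores: dict[str, float] = {}
    max_p = max(MODEL_P[m] for m in models)
    if curve.k <= max_p + 1:
        raise DomainError(f"need K > {max_p + 1} samples to compare all candidate models")
    for m in models:
        try:
            res = fit_nls(curve, m, boxes.get(m), n_starts=n_starts)
            scores[m] = aicc(max(res.sse, np.finfo(float).tiny), curve.k, MODEL_P[m])
        except Exception:
            return "unclassified", scores
    ordered = sorted(models, key=lambda m: MODEL_P[m])  # parsimony tie-break
    best = min(ordered, key=lambda m: (scores[m], MODEL_P[m]))
    for m in ordered:
        if scores[m] - scores[best] < _AICC_TIE_TOL:
            best = m
            break
    return best, scores


def classification_percentages(labels) -> dict[str, float]:
    """Percentage of voxels per selected-model label (sums to 100)."""
    labels = list(labels)
    if not labels:
        raise ConfigError("no labels to tally")
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return {lab: 100.0 * n / len(labels) for lab, n in out.items()}
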