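"""Regularization penalties for MHN training.

All penalties act on the off-diagonal entries of the event rows and (by
default) on the observation row; diagonal entries — the base rates — are
never penalized, since they set the overall time scale of the process and
shrinking them would bias all dynamics rather than simplify the interaction
structure.

The absolute value in the l1 and symmetric penalties is smoothed as
sqrt(t^2 + eps^2) - eps so that a smooth quasi-Newton optimizer applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import MutualHazardNetwork, ValidationError

__all__ = ["PenaltySpec", "penalty_value_and_gradient"]

PENALTY_KINDS = ("l1", "l2", "symmetric", "custom")

# custom hooks receive log_theta and return (value, gradient matrix)
CustomHook = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class PenaltySpec:
    """Which penalty to apply and how strongly.

    Parameters
    ----------
    kind
        ``l1`` drives small interactions to zero (sparse, interpretable
        networks); ``l2`` shrinks all interactions toward zero without
        sparsity; ``symmetric`` couples each pair (theta_ij, theta_ji) in a
        group penalty so the two directions of an interaction vanish or
        survive together; ``custom`` delegates to ``custom_hook``.
    strength
        Non-negative multiplier on the penalty in the objective.
    smoothing
        eps in the smoothed absolute value; default 1e-4.
    penalize_observation
        Whether the observation row is penalized (default True).
    custom_hook
        Required iff ``kind == "custom"``; maps log_theta to
        ``(value, gradient)``.
    """

    kind: str = "l1"
    strength: float = 0.0
    smoothing: float = 1e-4
    penalize_observation: bool = True
    custom_hook: CustomHook | None = None

    def __post_init__(self) -> None:
        if self.kind not in PENALTY_KINDS:
            raise ValidationError(f"penalty kind must be one of {PENALTY_KINDS}")
        if self.strength < 0:
            raise ValidationError("penalty strength must be >= 0")
        if self.smoothing <= 0:
            raise ValidationError("smoothing eps must be > 0")
        if (self.custom_hook is not None) != (self.kind == "custom"):
            raise ValidationError("custom_hook must be given iff kind='custom'")


def _smooth_abs(t: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    root = np.sqrt(t * t + eps * eps)
    return root - eps, t / root


def _penalized_mask(n: int, kind: str, obs: bool) -> np.ndarray:
    mask = np.ones((n + 1, n), dtype=bool)
    mask[np.arange(n), np.arange(n)] = False
    if not obs or kind == "classic":
        mask[n] = False
    return mask


def penalty_value_and_gradient(
    model: MutualHazardNetwork, spec: PenaltySpec
) -> tuple[float, np.ndarray]:
    """Penalty value and its exact gradient w.r.t. every log_theta entry.

    The returned value excludes the strength multiplier; callers scale by
    ``spec.strength``.
    """
    th = model.log_theta
    n = model.n
    eps = spec.smoothing
    mask = _penalized_mask(n, model.kind, spec.penalize_observation)
    G = np.zeros_like(th)

    if spec.kind == "custom":
        value, G = spec.custom_hook(th)
        G = np.asarray(G, dtype=float)
        if G.shape != th.shape:
            raise ValidationError(
                f"custom penalty gradient has shape {G.shape}, expected {th.shape}"
            )
        return float(value), G

    if spec.kind == "l2":
        G[mask] = 2.0 * th[mask]
        return float(np.sum(th[mask] ** 2)), G

    if spec.kind == "l1":
        val, dval = _smooth_abs(th[mask], eps)
        G[mask] = dval
        return float(val.sum()), G

    # symmetric: group penalty sqrt(th_ij^2 + th_ji^2 + eps^2) - eps over
    # unordered event pairs, plus smoothed l1 on the observation row.
    iu, ju = np.triu_indices(n, k=1)
    a, b = th[iu, ju], th[ju, iu]
    root = np.sqrt(a * a + b * b + eps * eps)
    value = float(np.sum(root - eps))
    G[iu, ju] = a / root
    G[ju, iu] = b / root
    if mask[n].any():
        v_obs, d_obs = _smooth_abs(th[n], eps)
        value += float(v_obs.sum())
        G[n] = d_obs
    return value, G
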