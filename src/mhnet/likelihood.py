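"""Exact marginal genotype probabilities, log-likelihood and analytic gradient.

The probability of observing genotype ``x`` is the probability that the chain,
started healthy, is absorbed by the observation event while sitting in state
``x``:

    p(x) = omega(x) * q(x),

where ``q`` solves the triangular flow recurrence

    q(0) = 1 / R(0),
    q(y) = [ sum over active i of lambda_i(y - e_i) q(y - e_i) ] / R(y).

State space restriction evaluates this recurrence only on the 2^k subsets of
the observed genotype (k = number of active events); because exit rates R(y)
still count all n events plus observation, the result equals the full 2^n
computation exactly. The gradient is computed per sample with one forward and
one adjoint (transposed) triangular solve.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from ._lattice import back_substitute, build_lattice, forward_substitute
from .model import Dataset, MutualHazardNetwork, ValidationError, as_genotype

__all__ = [
    "marginal_distribution_full",
    "genotype_probability",
    "log_likelihood",
    "gradient_log_likelihood",
    "count_states",
]

_FULL_STATE_GUARD = 20  # 2^n states; full enumeration is a test oracle

#: Minimum representable per-genotype probability before we refuse to
#: continue: probabilities are kept in linear space (k <= 32 with moderate
#: parameters does not underflow), so dropping below ~1e-300 signals a
#: pathological parameter matrix rather than a rounding issue.
_UNDERFLOW = 1e-300

_counter: dict | None = None


@contextmanager
def count_states():
    """Count lattice states touched by likelihood computations (diagnostics).

    >>> with count_states() as c:
    ...     genotype_probability(model, x)
    >>> c["states"]
    """
    global _counter
    prev, _counter = _counter, {"states": 0}
    try:
        yield _counter
    finally:
        _counter = prev


def _tally(size: int) -> None:
    if _counter is not None:
        _counter["states"] += size


def marginal_distribution_full(model: MutualHazardNetwork) -> np.ndarray:
    """Probability of every genotype, indexed by integer code (bit i = event i).

    Full 2^n enumeration; guarded at n <= 20 and intended as the exact oracle
    for tests and for small models.
    """
    n = model.n
    if n > _FULL_STATE_GUARD:
        raise ValidationError(
            f"full state space enumeration is limited to n <= {_FULL_STATE_GUARD}"
        )
    lat = build_lattice(model.log_theta, model.kind, np.arange(n))
    _tally(lat.size)
    q = forward_substitute(lat)
    return lat.omega * q


def genotype_probability(model: MutualHazardNetwork, x) -> float:
    """Exact p(x) via state space restriction to the 2^k sub-lattice."""
    x = as_genotype(x, model.n)
    active = np.flatnonzero(x)
    lat = build_lattice(model.log_theta, model.kind, active)
    _tally(lat.size)
    q = forward_substitute(lat)
    p = float(lat.omega[-1] * q[-1])
    if p < _UNDERFLOW:
        raise FloatingPointError(
            f"genotype probability underflowed ({p!r}); the parameter matrix "
            "is too extreme for linear-space computation"
        )
    return p


def log_likelihood(model: MutualHazardNetwork, data: Dataset) -> float:
    """Sum of log genotype probabilities over the cohort.

    Identical genotypes are aggregated by count first: the value is unchanged
    and the number of triangular solves drops to the number of distinct
    genotypes.
    """
    uniq, counts = data.aggregate()
    total = 0.0
    for row, c in zip(uniq, counts):
        total += c * np.log(genotype_probability(model, row))
    return float(total)


def gradient_log_likelihood(model: MutualHazardNetwork, data: Dataset) -> np.ndarray:
    """Exact gradient of :func:`log_likelihood` w.r.t. every log_theta entry.

    For the classic kind the observation row is inactive and returned as zero.
    """
    uniq, counts = data.aggregate()
    G = np.zeros_like(model.log_theta)
    for row, c in zip(uniq, counts):
        _, g = _logp_and_grad(model, row)
        G += c * g
    return G


def _logp_and_grad(model: MutualHazardNetwork, x) -> tuple[float, np.ndarray]:
    """log p(x) and its gradient from one forward and one adjoint solve.

    Three contribution groups:
    (a) within-lattice transition rates lambda_{A[b]}(y_s),
    (b) diagonal exit rates R(s) -- including rates of events outside the
        active set, whose theta rows influence R even though the events never
        fire inside the lattice,
    (c) the absorption factor omega(x).
    """
    x = as_genotype(x, model.n)
    n = model.n
    active = np.flatnonzero(x)
    k = active.size
    lat = build_lattice(model.log_theta, model.kind, active)
    _tally(lat.size)
    q = forward_substitute(lat)
    top = lat.size - 1
    if lat.omega[top] * q[top] < _UNDERFLOW:
        raise FloatingPointError("genotype probability underflowed in gradient")
    r = back_substitute(lat, top)
    logp = float(np.log(lat.omega[top]) + np.log(q[top]))

    G = np.zeros((n + 1, n))
    Y, lam = lat.Y, lat.lam
    # (b) exit-rate terms: d log q / d R(s) = -r_s q_s / q_top
    w = r * q / q[top]  # (2^k,)
    A = (w[:, None] * (1.0 - Y)) * lam  # rate-weighted, inactive events only
    G[:n] -= A.T @ Y
    G[np.arange(n), np.arange(n)] -= A.sum(axis=0)
    if model.kind != "classic":
        G[n] -= (w * lat.omega) @ Y
        # (c) absorption factor omega(x)
        G[n] += x
    # (a) transition terms: d log q / d lambda_{A[b]}(s) = r_{s|b} q_s / q_top
    states = np.arange(lat.size, dtype=np.int64)
    for b in range(k):
        src = states[(states >> b) & 1 == 0]
        coef = r[src | (1 << b)] * q[src] * lat.lam_act[src, b] / q[top]
        i = active[b]
        G[i] += coef @ Y[src]
        G[i, i] += coef.sum()
    return logp, G
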