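"""Shared sub-lattice machinery for exact likelihood, gradient and histories.

For a conditioning genotype with active event set ``A`` (|A| = k), the chain
restricted to states below that genotype lives on the 2^k subsets of ``A``.
State ``s`` (an integer, bit ``b`` of ``s`` <-> event ``A[b]``) gains bits one
at a time, so the flow system ``(diag(R) - T) q = e_0`` is lower triangular in
natural integer order and solved exactly by forward substitution.

Exit rates R(s) are computed over ALL n events and the observation event, not
just the k restricted ones: probability mass leaving the sub-lattice through
an out-of-lattice event is exactly what makes the restricted computation equal
to the full 2^n computation rather than an approximation of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Lattice", "build_lattice"]


@dataclass
class Lattice:
    """Rates of the 2^k sub-lattice below one genotype.

    Attributes
    ----------
    active : (k,) int array of the conditioning genotype's event indices.
    Y : (2^k, n) float; ``Y[s]`` is the full-length genotype of state ``s``.
    lam : (2^k, n) float; ``lam[s, i]`` = rate of event ``i`` out of state
        ``s`` (meaningful for events inactive in ``s``).
    lam_act : (2^k, k) float; ``lam[:, active]`` for transition lookups.
    omega : (2^k,) observation rate per state.
    R : (2^k,) total exit rate per state.
    """

    active: np.ndarray
    Y: np.ndarray
    lam: np.ndarray
    lam_act: np.ndarray
    omega: np.ndarray
    R: np.ndarray

    @property
    def size(self) -> int:
        return self.R.shape[0]

    @property
    def k(self) -> int:
        return self.active.shape[0]


def build_lattice(log_theta: np.ndarray, kind: str, active: np.ndarray) -> Lattice:
    """Precompute per-state rates for the sub-lattice spanned by ``active``."""
    n = log_theta.shape[1]
    active = np.asarray(active, dtype=np.int64)
    k = active.size
    size = 1 << k
    states = np.arange(size, dtype=np.int64)
    bits = ((states[:, None] >> np.arange(k)) & 1).astype(float)  # (2^k, k)
    Y = np.zeros((size, n))
    if k:
        Y[:, active] = bits

    th = log_theta[:n]
    # log lam[s, i] = theta_ii + sum over active j != i of theta_ij
    log_lam = Y @ th.T + np.diag(th) * (1.0 - Y)
    lam = np.exp(log_lam)
    if kind == "classic":
        omega = np.ones(size)
    else:
        omega = np.exp(Y @ log_theta[n])
    R = omega + ((1.0 - Y) * lam).sum(axis=1)
    lam_act = lam[:, active] if k else np.zeros((size, 0))
    return Lattice(active, Y, lam, lam_act, omega, R)


def forward_substitute(lat: Lattice) -> np.ndarray:
    """Solve (diag(R) - T) q = e_0 bottom-up; q[s] is the probability flow
    into state ``s`` divided by its exit rate (time-integrated occupancy)."""
    size = lat.size
    q = np.zeros(size)
    q[0] = 1.0 / lat.R[0]
    lam_act, R = lat.lam_act, lat.R
    for s in range(1, size):
        acc = 0.0
        t = s
        while t:
            b = (t & -t).bit_length() - 1
            ps = s & ~(1 << b)
            acc += lam_act[ps, b] * q[ps]
            t &= t - 1
        q[s] = acc / R[s]
    return q


def back_substitute(lat: Lattice, target: int) -> np.ndarray:
    """Solve the transposed system (diag(R) - T)^T r = e_target top-down.

    ``r[s]`` is the sensitivity of the flow at ``target`` to unit mass
    injected at ``s`` (the adjoint of :func:`forward_substitute`).
    """
    size = lat.size
    r = np.zeros(size)
    lam_act, R, k = lat.lam_act, lat.R, lat.k
    for s in range(size - 1, -1, -1):
        acc = 1.0 if s == target else 0.0
        for b in range(k):
            if not (s >> b) & 1:
                acc += lam_act[s, b] * r[s | (1 << b)]
        r[s] = acc / R[s]
    return r
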