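"""Gillespie sampling of artificial tumor histories from a trained MHN.

Each tumor starts healthy, waits an Exp(R(x))-distributed time in its current
genotype x, then either gets observed (probability omega(x)/R(x)) or acquires
one of the remaining events i (probability lambda_i(x)/R(x)); the walk stops
at observation, which happens with probability 1 since omega > 0. The full
ordered, time-stamped event sequence is retained so questions about the order
of accumulation can be answered, not just the final genotype.

The simulator and the likelihood engine are independent derivations of the
same law, which makes their agreement on empirical genotype frequencies the
strongest internal cross-check in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Dataset, MutualHazardNetwork, ValidationError

__all__ = ["History", "sample_history", "sample_dataset"]


@dataclass
class History:
    """One simulated tumor: ordered events with times, ending in observation."""

    steps: tuple[tuple[str, float], ...]  # (event label, occurrence time)
    observation_time: float
    final_genotype: np.ndarray

    def __post_init__(self) -> None:
        times = [t for _, t in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("step times must be strictly increasing")
        if times and times[-1] >= self.observation_time:
            raise ValidationError("all step times must precede observation")

    def to_json_dict(self, sample_id: str | None = None) -> dict:
        rec = {
            "events": [{"label": lbl, "time": t} for lbl, t in self.steps],
            "observed_at": self.observation_time,
        }
        if sample_id is not None:
            rec = {"id": sample_id, **rec}
        return rec


def sample_history(model: MutualHazardNetwork, rng: np.random.Generator) -> History:
    """Draw one complete tumor history by competing exponentials.

    The categorical choice at each step uses a single uniform draw compared
    against cumulative rate fractions in fixed event-index order with
    observation last, so histories are bit-reproducible for a given stream.
    """
    n = model.n
    th = model.log_theta
    diag = np.diag(th[:n])
    x = np.zeros(n, dtype=np.int8)
    t = 0.0
    steps: list[tuple[str, float]] = []
    for _ in range(n + 1):
        # lambda_i(x) for inactive i, zero for active i
        log_rates = diag * (1 - x) + th[:n] @ x
        rates = np.exp(log_rates) * (1 - x)
        omega = 1.0 if model.kind == "classic" else float(np.exp(th[n] @ x))
        total = rates.sum() + omega
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        cum = np.cumsum(rates)
        hit = np.searchsorted(cum, u, side="right")
        if hit >= n or u >= cum[-1]:  # observation (last in the ordering)
            return History(tuple(steps), t, x.copy())
        x[hit] = 1
        steps.append((model.catalog.names[hit], t))
    raise AssertionError("walk did not terminate within n+1 steps")  # pragma: no cover


def sample_dataset(
    model: MutualHazardNetwork,
    N: int,
    seed: int,
    keep_histories: bool = False,
) -> Dataset | tuple[Dataset, list[History]]:
    """Sample a cross-sectional cohort of N independent tumors.

    Each draw gets its own rng stream derived from ``(seed, draw index)``, so
    any prefix of the cohort is reproducible independent of N.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    genotypes = np.zeros((N, model.n), dtype=np.int8)
    histories: list[History] = []
    for i in range(N):
        rng = np.random.default_rng([seed, i])
        h = sample_history(model, rng)
        genotypes[i] = h.final_genotype
        if keep_histories:
            histories.append(h)
    ids = tuple(f"S{i:06d}" for i in range(N))
    data = Dataset(genotypes, model.catalog, ids)
    return (data, histories) if keep_histories else data
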