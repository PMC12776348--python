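"""Core data structures and elementary rates of a Mutual Hazard Network.

A Mutual Hazard Network (MHN) models tumor progression as a continuous-time
Markov chain on the Boolean lattice {0,1}^n: a tumor starts with no events,
acquires binary progression events irreversibly, and is eventually observed
(diagnosed) at a rate that itself depends on the accumulated genotype.

The model is parameterized by an (n+1) x n matrix on natural-log scale:

* diagonal entries ``theta[i, i]`` -- log base rate of event ``i`` when no
  other event is present;
* off-diagonal entries ``theta[i, j]`` -- log multiplicative effect of a
  present event ``j`` on the rate of event ``i`` (the "mutual hazard");
* bottom row ``theta[n, j]`` -- log multiplicative effect of event ``j`` on
  the observation rate.

The observation event's own base rate is fixed to 1 (log 0): the process is
identified only up to a global time scale, so this rate is absorbed into the
time unit rather than fitted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HARD_EVENT_LIMIT",
    "SOFT_EVENT_LIMIT",
    "ValidationError",
    "CatalogMismatchError",
    "EventLimitError",
    "EventCatalog",
    "MutualHazardNetwork",
    "Dataset",
    "as_genotype",
    "initial_theta",
]

#: Hard cap on simultaneously active events per sample. The restricted state
#: space has 2^k states for k active events and states are encoded as machine
#: integers bit-by-bit, so 32 is the technical ceiling.
HARD_EVENT_LIMIT = 32

#: Above this many active events a warning is emitted: computations remain
#: exact but the 2^k per-sample cost becomes the dominant expense.
SOFT_EVENT_LIMIT = 25

KINDS = ("observation_aware", "classic")

_MODEL_FORMAT_VERSION = 1


class ValidationError(ValueError):
    """Invalid user input (malformed dataset, model file, or arguments)."""


class CatalogMismatchError(ValidationError):
    """Genotype or dataset does not match the model's event catalog."""


class EventLimitError(ValidationError):
    """A sample has more active events than the hard technical limit."""


@dataclass(frozen=True)
class EventCatalog:
    """Ordered collection of the n distinct progression-event labels."""

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        names = tuple(str(x) for x in names)
        if len(names) == 0:
            raise ValidationError("event catalog must contain at least one event")
        if any(not name for name in names):
            raise ValidationError("event labels must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValidationError(f"duplicate event labels: {dupes}")
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise ValidationError(f"unknown event label: {label!r}") from None

    def __len__(self) -> int:
        return self.n


def as_genotype(bits: Sequence[int] | np.ndarray, n: int | None = None) -> np.ndarray:
    """Coerce ``bits`` to a validated 0/1 integer vector.

    Enforces the hard limit of 32 active events and warns above 25.
    """
    x = np.asarray(bits)
    if x.ndim != 1:
        raise ValidationError(f"genotype must be a vector, got shape {x.shape}")
    if not np.isin(x, (0, 1)).all():
        bad = x[~np.isin(x, (0, 1))][0]
        raise ValidationError(f"genotype entries must be 0 or 1, got {bad!r}")
    x = x.astype(np.int8)
    if n is not None and x.size != n:
        raise CatalogMismatchError(f"genotype has {x.size} events, expected {n}")
    k = int(x.sum())
    if k > HARD_EVENT_LIMIT:
        raise EventLimitError(
            f"sample has {k} active events; the technical limit is "
            f"{HARD_EVENT_LIMIT} active events per observation"
        )
    if k > SOFT_EVENT_LIMIT:
        warnings.warn(
            f"sample has {k} active events (> {SOFT_EVENT_LIMIT}); the exact "
            f"computation scales as 2^k per sample and will be slow",
            RuntimeWarning,
            stacklevel=2,
        )
    return x


@dataclass
class MutualHazardNetwork:
    """An MHN: log-scale parameter matrix plus event catalog and model kind.

    Parameters
    ----------
    log_theta
        ``(n+1, n)`` array. Rows ``0..n-1`` parameterize event rates, row
        ``n`` the observation rate (ignored and kept at zero for the
        ``classic`` kind).
    catalog
        The event labels, one per column.
    kind
        ``"observation_aware"`` (default) models diagnosis as a competing
        event with genotype-dependent rate; ``"classic"`` reproduces the
        earlier MHN variant with a constant observation rate of 1.
    """

    log_theta: np.ndarray
    catalog: EventCatalog
    kind: str = "observation_aware"

    def __post_init__(self) -> None:
        th = np.asarray(self.log_theta, dtype=float)
        n = self.catalog.n
        if th.shape != (n + 1, n):
            raise ValidationError(
                f"log_theta must have shape {(n + 1, n)}, got {th.shape}"
            )
        if not np.isfinite(th).all():
            raise ValidationError("log_theta entries must be finite")
        if self.kind not in KINDS:
            raise ValidationError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.log_theta = th

    # -- construction -------------------------------------------------------

    @classmethod
    def zeros(cls, catalog: EventCatalog | Sequence[str], kind: str = "observation_aware"):
        if not isinstance(catalog, EventCatalog):
            catalog = EventCatalog(catalog)
        return cls(np.zeros((catalog.n + 1, catalog.n)), catalog, kind)

    @property
    def n(self) -> int:
        return self.catalog.n

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape != (self.n,):
            raise CatalogMismatchError(
                f"genotype has shape {x.shape}, expected ({self.n},)"
            )
        return x

    # -- elementary rates ----------------------------------------------------

    def event_rate(self, x: Sequence[int] | np.ndarray, i: int) -> float:
        """Rate lambda_i(x) = exp(theta_ii + sum_{j != i, x_j = 1} theta_ij).

        Defined for any genotype ``x``; callers are responsible for only
        querying events that have not yet occurred.
        """
        x = self._check(x)
        if not 0 <= i < self.n:
            raise IndexError(f"event index {i} out of range [0, {self.n})")
        row = self.log_theta[i]
        log_rate = row[i] + float(row @ x) - row[i] * x[i]
        return float(np.exp(log_rate))

    def observation_rate(self, x: Sequence[int] | np.ndarray) -> float:
        """Observation rate omega(x); constant 1 for the classic kind."""
        x = self._check(x)
        if self.kind == "classic":
            return 1.0
        return float(np.exp(self.log_theta[self.n] @ x))

    def total_exit_rate(self, x: Sequence[int] | np.ndarray) -> float:
        """R(x) = omega(x) + sum over inactive events i of lambda_i(x)."""
        x = self._check(x)
        total = self.observation_rate(x)
        for i in range(self.n):
            if x[i] == 0:
                total += self.event_rate(x, i)
        return total

    # -- display -------------------------------------------------------------

    def multipliers(self) -> np.ndarray:
        """exp(log_theta): base rates and rate multipliers for display."""
        return np.exp(self.log_theta)

    # -- serialization -------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "version": _MODEL_FORMAT_VERSION,
            "kind": self.kind,
            "events": list(self.catalog.names),
            "log_theta": [[float(v) for v in row] for row in self.log_theta],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1) + "\n")

    @classmethod
    def from_json_dict(cls, obj: dict) -> "MutualHazardNetwork":
        try:
            catalog = EventCatalog(obj["events"])
            th = np.asarray(obj["log_theta"], dtype=float)
            kind = obj["kind"]
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed model file: {exc}") from exc
        return cls(th, catalog, kind)

    @classmethod
    def load(cls, path: str | Path) -> "MutualHazardNetwork":
        try:
            obj = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"model file is not valid JSON: {exc}") from exc
        return cls.from_json_dict(obj)


@dataclass
class Dataset:
    """Cross-sectional cohort: one binary genotype per tumor sample."""

    genotypes: np.ndarray  # (N, n) int8
    catalog: EventCatalog
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[1] != self.catalog.n:
            raise ValidationError(
                f"genotype matrix must be (N, {self.catalog.n}), got {g.shape}"
            )
        ok = np.isin(g, (0, 1))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype entries must be 0 or 1; row {r} "
                f"(event {self.catalog.names[c]!r}) has {g[r, c]!r}"
            )
        g = g.astype(np.int8)
        counts = g.sum(axis=1)
        if (counts > HARD_EVENT_LIMIT).any():
            r = int(np.argmax(counts > HARD_EVENT_LIMIT))
            raise EventLimitError(
                f"sample {r} has {counts[r]} active events; the technical limit "
                f"is {HARD_EVENT_LIMIT} active events per observation"
            )
        if (counts > SOFT_EVENT_LIMIT).any():
            warnings.warn(
                f"{int((counts > SOFT_EVENT_LIMIT).sum())} sample(s) have more "
                f"than {SOFT_EVENT_LIMIT} active events; exact computation "
                f"scales as 2^k per sample and will be slow",
                RuntimeWarning,
                stacklevel=2,
            )
        self.genotypes = g
        if self.sample_ids is not None:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
            if len(self.sample_ids) != len(self.genotypes):
                raise ValidationError(
                    f"{len(self.sample_ids)} sample ids for "
                    f"{len(self.genotypes)} genotypes"
                )

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def n(self) -> int:
        return self.catalog.n

    def aggregate(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique genotypes and their counts, sorted by integer genotype code.

        Bit ``j`` of the code is event ``j``, so the order is deterministic
        and independent of row order in the input.
        """
        if len(self) == 0:
            raise ValidationError("dataset is empty")
        codes = self.genotypes.astype(np.int64) @ (1 << np.arange(self.n, dtype=np.int64))
        order = np.argsort(codes, kind="stable")
        uniq_codes, first, counts = np.unique(
            codes[order], return_index=True, return_counts=True
        )
        return self.genotypes[order][first], counts

    def subset(self, idx: Sequence[int] | np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        ids = tuple(np.asarray(self.sample_ids, dtype=object)[idx]) \
            if self.sample_ids is not None else None
        return Dataset(self.genotypes[idx], self.catalog, ids)


def initial_theta(data: Dataset, kind: str = "observation_aware") -> MutualHazardNetwork:
    """Independence initialization for the optimizer.

    Diagonal entries are the logit of each event's marginal frequency,
    ``theta_ii = ln(f_i / (1 - f_i))``, which is the exact classic-model MLE
    for a single event with no interactions (p = lambda / (1 + lambda)).
    Frequencies are clipped to ``[1/(2N), 1 - 1/(2N)]`` so never-seen and
    always-seen events get finite rates. All other entries start at zero.
    """
    if len(data) == 0:
        raise ValidationError("dataset is empty")
    n, N = data.n, len(data)
    freq = data.genotypes.mean(axis=0)
    freq = np.clip(freq, 1.0 / (2 * N), 1.0 - 1.0 / (2 * N))
    th = np.zeros((n + 1, n))
    np.fill_diagonal(th[:n], np.log(freq / (1.0 - freq)))
    return MutualHazardNetwork(th, data.catalog, kind)
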