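"""Stochastic simulation of single-receptor binding/unbinding traces.

A single receptor sits in a mixture of ligand species. While unbound, it
binds at total rate ``sum_i k_i c_i``; the identity of the binding ligand is
drawn with probability proportional to ``k_i c_i``; the bound interval is
exponential with that species' unbinding rate ``r_i``.  For this two-state
receptor the exact (Gillespie) simulation reduces to direct sequential
sampling of exponential and categorical variates, which is what we do.

The module also provides an exact stochastic simulator for messenger
birth-death processes driven by the receptor occupancy (optionally gated on
the receptor having been bound longer than a cutoff), used to validate the
closed-form kinetic-proofreading readout moments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LigandSpecies",
    "LigandMixture",
    "BindingTrace",
    "MessengerParams",
    "MessengerStats",
    "sample_trace",
    "sample_trace_duration",
    "simulate_messengers",
]


@dataclass(frozen=True)
class LigandSpecies:
    """One ligand species: binding rate ``k`` (per concentration per time),
    unbinding rate ``r`` (per time) and concentration ``c``."""

    label: str
    k: float
    r: float
    c: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"binding rate k must be > 0, got {self.k}")
        if not self.r > 0:
            raise ValueError(f"unbinding rate r must be > 0, got {self.r}")
        if self.c < 0:
            raise ValueError(f"concentration c must be >= 0, got {self.c}")


@dataclass(frozen=True)
class LigandMixture:
    """An ordered collection of ligand species.

    By convention species are ordered by decreasing binding duration, i.e.
    increasing unbinding rate; for the two-species case the first species is
    the cognate one (r_c < r_nc).
    """

    species: tuple[LigandSpecies, ...]

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("mixture needs at least one species")
        r = [s.r for s in self.species]
        if any(b < a for a, b in zip(r, r[1:])):
            raise ValueError(
                "species must be ordered by increasing unbinding rate"
            )

    @classmethod
    def two_species(
        cls,
        k_c: float,
        r_c: float,
        c_c: float,
        k_nc: float,
        r_nc: float,
        c_nc: float,
    ) -> "LigandMixture":
        return cls(
            (
                LigandSpecies("cognate", k_c, r_c, c_c),
                LigandSpecies("noncognate", k_nc, r_nc, c_nc),
            )
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.species)

    @property
    def k(self) -> np.ndarray:
        return np.array([s.k for s in self.species])

    @property
    def r(self) -> np.ndarray:
        return np.array([s.r for s in self.species])

    @property
    def c(self) -> np.ndarray:
        return np.array([s.c for s in self.species])

    @property
    def on_rates(self) -> np.ndarray:
        """Per-species on-rates k_i c_i."""
        return self.k * self.c

    @property
    def total_on_rate(self) -> float:
        return float(np.sum(self.on_rates))

    def with_concentrations(self, c: Sequence[float]) -> "LigandMixture":
        """A copy of this mixture with new concentrations (rates kept)."""
        if len(c) != len(self.species):
            raise ValueError("length of c must match number of species")
        return LigandMixture(
            tuple(
                LigandSpecies(s.label, s.k, s.r, float(ci))
                for s, ci in zip(self.species, c)
            )
        )

    def to_json(self, path) -> None:
        obj = {
            "species": [
                {"label": s.label, "k": s.k, "r": s.r, "c": s.c}
                for s in self.species
            ]
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LigandMixture":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            tuple(
                LigandSpecies(d["label"], d["k"], d["r"], d["c"])
                for d in obj["species"]
            )
        )


@dataclass
class BindingTrace:
    """An ordered sequence of bound/unbound interval durations.

    ``tau_b[i]`` is the i-th bound duration and ``tau_u[i]`` the unbound
    duration following it.  The last unbound interval wraps around: it is the
    sum of the lead-in segment before the first binding and the tail segment
    after the last unbinding, so that ``T = sum(tau_b) + sum(tau_u)``.

    ``true_species`` is simulator bookkeeping (per-event ligand labels) and
    must never be consulted by estimators.
    """

    tau_b: np.ndarray
    tau_u: np.ndarray
    true_species: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tau_b = np.asarray(self.tau_b, dtype=float)
        self.tau_u = np.asarray(self.tau_u, dtype=float)
        if self.tau_b.shape != self.tau_u.shape or self.tau_b.ndim != 1:
            raise ValueError("tau_b and tau_u must be 1-d arrays of equal length")
        if self.n == 0:
            raise ValueError("empty trace")
        if np.any(self.tau_b <= 0) or np.any(self.tau_u <= 0):
            raise ValueError("all interval durations must be positive")
        if self.true_species is not None:
            self.true_species = np.asarray(self.true_species)
            if len(self.true_species) != self.n:
                raise ValueError("true_species length must equal n")

    @property
    def n(self) -> int:
        """Number of binding events."""
        return len(self.tau_b)

    @property
    def Tu(self) -> float:
        """Total unbound time."""
        return float(np.sum(self.tau_u))

    @property
    def T(self) -> float:
        """Total duration of the trace."""
        return float(np.sum(self.tau_b)) + self.Tu

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "event_index": np.arange(self.n),
                "tau_b": self.tau_b,
                "tau_u": self.tau_u,
            }
        )
        if self.true_species is not None:
            df["species"] = self.true_species
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BindingTrace":
        df = pd.read_csv(path, sep="\t")
        species = df["species"].to_numpy() if "species" in df.columns else None
        return cls(
            df["tau_b"].to_numpy(), df["tau_u"].to_numpy(), true_species=species
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_trace(
    mixture: LigandMixture, n_events: int, seed=None
) -> BindingTrace:
    """Draw a trace of exactly ``n_events`` binding events.

    Unbound intervals are iid Exponential(total on-rate); each binding event
    is attributed to species i with probability k_i c_i / (sum k_j c_j) and
    lasts an Exponential(r_i) time.  The wrap-around convention for the last
    unbound interval is automatic here: all n unbound intervals are iid, and
    the n-th one stands for the combined lead-in/tail segment.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    K = mixture.total_on_rate
    if K <= 0:
        raise ValueError("no binding possible: total on-rate is zero")
    rng = _rng(seed)
    tau_u = rng.exponential(1.0 / K, size=n_events)
    p = mixture.on_rates / K
    idx = rng.choice(len(mixture.species), size=n_events, p=p)
    tau_b = rng.exponential(1.0, size=n_events) / mixture.r[idx]
    labels = np.array(mixture.labels)[idx]
    return BindingTrace(tau_b, tau_u, true_species=labels)


def sample_trace_duration(
    mixture: LigandMixture, T: float, seed=None
) -> BindingTrace:
    """Draw a trace of fixed total duration ``T`` (variable event count).

    The receptor starts unbound; simulation runs until the clock passes T.
    A bound interval straddling T is truncated at T and dropped (the trace
    convention ends on an unbinding event), and the lead-in unbound
    segment plus the tail after the last unbinding are merged into the final
    unbound interval.  Not used by the acceptance studies, which fix the
    number of events instead.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    K = mixture.total_on_rate
    if K <= 0:
        raise ValueError("no binding possible: total on-rate is zero")
    rng = _rng(seed)
    p = mixture.on_rates / K
    labels = np.array(mixture.labels)
    lead = rng.exponential(1.0 / K)
    t = lead
    tau_b, tau_u, spec = [], [], []
    while True:
        i = rng.choice(len(mixture.species), p=p)
        b = rng.exponential(1.0 / mixture.r[i])
        if t + b >= T:
            break
        t += b
        u = rng.exponential(1.0 / K)
        if t + u >= T:
            tau_b.append(b)
            spec.append(labels[i])
            tau_u.append(T - t)  # tail only; lead merged below
            t = T
            break
        tau_b.append(b)
        spec.append(labels[i])
        tau_u.append(u)
        t += u
    if not tau_b:
        raise ValueError("no complete binding event fits in T; increase T")
    if t < T:  # loop broke on a straddling bound interval
        tau_u[-1] += T - t
    tau_u[-1] += lead  # wrap-around of the last unbound interval
    return BindingTrace(
        np.array(tau_b), np.array(tau_u), true_species=np.array(spec)
    )


@dataclass(frozen=True)
class MessengerParams:
    """A first-order messenger: produced at ``k_prod`` while its gate holds,
    degraded at ``r_deg`` per molecule.

    gate="bound": production whenever the receptor is bound.
    gate="bound-longer-than-Tc": production once the current bound interval
    has lasted longer than ``Tc`` (the kinetic-proofreading delay).
    """

    k_prod: float
    r_deg: float
    gate: Literal["bound", "bound-longer-than-Tc"] = "bound"
    Tc: float = 0.0

    def __post_init__(self) -> None:
        if self.k_prod < 0:
            raise ValueError("k_prod must be >= 0")
        if not self.r_deg > 0:
            raise ValueError("r_deg must be > 0")
        if self.Tc < 0:
            raise ValueError("Tc must be >= 0")
        if self.gate not in ("bound", "bound-longer-than-Tc"):
            raise ValueError(f"unknown gate {self.gate!r}")


@dataclass(frozen=True)
class MessengerStats:
    """Time-averaged first two moments of a messenger copy number."""

    mean: float
    var: float
    total_time: float


def _ssa_segments(
    segments: list[tuple[float, float]], r_deg: float, rng: np.random.Generator
) -> MessengerStats:
    """Exact SSA for a birth-death process with piecewise-constant birth rate.

    ``segments`` is a list of (duration, production_rate).  Accumulates the
    time integrals of N and N^2 for time-averaged mean and variance.
    """
    n = 0
    acc1 = 0.0
    acc2 = 0.0
    total = 0.0
    for dur, prod in segments:
        t = 0.0
        while True:
            rate = prod + n * r_deg
            if rate <= 0.0:
                dt = dur - t
                acc1 += n * dt
                acc2 += n * n * dt
                break
            dt = rng.exponential(1.0 / rate)
            if t + dt >= dur:
                dt = dur - t
                acc1 += n * dt
                acc2 += n * n * dt
                break
            acc1 += n * dt
            acc2 += n * n * dt
            t += dt
            if rng.random() < prod / rate:
                n += 1
            else:
                n -= 1
        total += dur
    mean = acc1 / total
    return MessengerStats(mean=mean, var=acc2 / total - mean * mean, total_time=total)


def simulate_messengers(
    trace: BindingTrace, params: Sequence[MessengerParams], seed=None
) -> list[MessengerStats]:
    """Exact stochastic simulation of messengers driven by a binding trace.

    Each messenger evolves independently given the trace: production is on
    during the gated portions of bound intervals, degradation is always on.
    Returns time-averaged mean and variance of each copy number over the
    trace duration.
    """
    if trace.n == 0:
        raise ValueError("empty trace")
    rng = _rng(seed)
    out = []
    for prm in params:
        segs: list[tuple[float, float]] = []
        for b, u in zip(trace.tau_b, trace.tau_u):
            if prm.gate == "bound":
                segs.append((b, prm.k_prod))
            else:
                if b > prm.Tc:
                    if prm.Tc > 0:
                        segs.append((prm.Tc, 0.0))
                    segs.append((b - prm.Tc, prm.k_prod))
                else:
                    segs.append((b, 0.0))
            segs.append((u, 0.0))
        out.append(_ssa_segments(segs, prm.r_deg, rng))
    return out
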