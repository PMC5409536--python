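"""Two-branch kinetic-proofreading readout of the threshold estimator.

A receptor drives two messengers: B is produced (rate k_B) whenever the
receptor is bound, A is produced (rate k_A) only once the receptor has been
bound longer than a proofreading delay Tc.  Both decay in first order.  The
mean levels are then occupancy-weighted closed forms, and inverting them
recovers the two ligand concentrations — exactly, or linearly in the
low-occupancy limit where the linearized forms mirror the threshold
estimator (the subtraction in c_nc^KPR is the incoherent-feedforward node).

With multiple proofreading intermediates the delay is random with variance
sigma_Tc^2, which to second order renormalizes the effective cutoff to
Tc_mean - r_c sigma_Tc^2 / 2.  The readout noise of the proofread branch is
dominated by the Poisson arrival of rare long binding events, filtered
through the messenger lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_sim import LigandMixture

__all__ = [
    "KPRNetwork",
    "KPRReadout",
    "mean_readouts",
    "invert_exact",
    "invert_linear",
    "renormalized_cutoff",
    "readout_relvar",
    "readout",
]


@dataclass(frozen=True)
class KPRNetwork:
    """Production/decay rates of the two messenger branches and the
    proofreading delay (mean and variance; zero variance = deterministic)."""

    kA: float
    kB: float
    rA: float
    rB: float
    Tc_mean: float
    Tc_var: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kA, self.kB, self.rA, self.rB) <= 0:
            raise ValueError("all rates must be positive")
        if self.Tc_mean < 0 or self.Tc_var < 0:
            raise ValueError("Tc_mean and Tc_var must be >= 0")


def _occupancy_terms(truth: LigandMixture):
    """Per-species k_i c_i / r_i and the occupancy denominator 1 + sum."""
    terms = truth.on_rates / truth.r
    return terms, 1.0 + float(np.sum(terms))


def mean_readouts(
    truth: LigandMixture, net: KPRNetwork
) -> tuple[float, float]:
    """Mean messenger levels at a deterministic delay Tc = Tc_mean:

        A = sum_i (k_i c_i / r_i) e^{-r_i Tc} / Q * kA/rA,
        B = sum_i (k_i c_i / r_i)            / Q * kB/rB,

    with Q = 1 + sum_i k_i c_i / r_i the occupancy denominator.
    """
    terms, Q = _occupancy_terms(truth)
    A = float(np.sum(terms * np.exp(-truth.r * net.Tc_mean))) / Q * net.kA / net.rA
    B = float(np.sum(terms)) / Q * net.kB / net.rB
    return A, B


def invert_exact(
    A_mean: float, B_mean: float, net: KPRNetwork, rates: LigandMixture
) -> tuple[float, float]:
    """Exact inversion of the mean readouts to concentrations.

    Treats all production of A as cognate-driven (valid for Tc >> 1/r_nc);
    under that reading the round trip through the cognate-only A mean is
    algebraically exact.  Raises when B saturates at its ceiling kB/rB.
    """
    if len(rates.species) != 2:
        raise ValueError("inversion supports exactly two species")
    ceiling = net.kB / net.rB
    if B_mean >= ceiling:
        raise ValueError(
            "B readout at or beyond its saturation ceiling kB/rB; "
            "occupancy correction diverges"
        )
    k_c, k_nc = rates.k
    r_c, r_nc = rates.r
    X = B_mean / (ceiling - B_mean)  # = sum_i k_i c_i / r_i
    growth = np.exp(r_c * net.Tc_mean) * net.rA / net.kA * (1.0 + X)
    c_c = A_mean * growth * r_c / k_c
    c_nc = (r_nc / k_nc) * (X - A_mean * growth)
    return float(c_c), float(c_nc)


def invert_linear(
    A_mean: float, B_mean: float, net: KPRNetwork, rates: LigandMixture
) -> tuple[float, float]:
    """Linearized inversion, valid when the occupancy eps = B/(kB/rB) << 1:

        c_c^KPR  = A e^{r_c Tc} r_c rA / (k_c kA),
        c_nc^KPR = (r_nc/k_nc) (rB B / kB - A e^{r_c Tc} rA / kA).

    The second line is a positive-weighted difference of the B and A
    readouts — biochemically, an incoherent feedforward subtraction node.
    """
    if len(rates.species) != 2:
        raise ValueError("inversion supports exactly two species")
    k_c, k_nc = rates.k
    r_c, r_nc = rates.r
    a_term = A_mean * np.exp(r_c * net.Tc_mean) * net.rA / net.kA
    c_c = a_term * r_c / k_c
    c_nc = (r_nc / k_nc) * (net.rB * B_mean / net.kB - a_term)
    return float(c_c), float(c_nc)


def renormalized_cutoff(net: KPRNetwork, rates: LigandMixture) -> float:
    """Effective cutoff under a random proofreading delay:
    Tc_mean - r_c sigma_Tc^2 / 2 (second-order in the delay spread).

    Using this value in place of Tc in the linearized inversion removes the
    bias introduced by delay randomness.
    """
    r_c = rates.r[0]
    return float(net.Tc_mean - 0.5 * r_c * net.Tc_var)


def expected_long_fraction(
    truth: LigandMixture, Tc_mean: float, Tc_var: float = 0.0
) -> float:
    """Expected fraction of binding events outlasting a (random) cutoff,
    in the regime Tc_mean >> 1/r_nc where long events are cognate:

        k_c c_c e^{-r_c Tc_mean + r_c^2 sigma_Tc^2 / 2} / (sum_i k_i c_i).
    """
    r_c = truth.r[0]
    K = truth.total_on_rate
    return float(
        truth.on_rates[0]
        * np.exp(-r_c * Tc_mean + 0.5 * r_c**2 * Tc_var)
        / K
    )


def readout_relvar(truth: LigandMixture, net: KPRNetwork) -> float:
    """Relative variance of the proofread readout, sigma_A^2 / A^2:

        (1 + sum_i k_i c_i/r_i) e^{r_c Tc - r_c^2 sigma_Tc^2/2}
        / (k_c c_c (1/r_c + 1/rA)).

    This is Poisson shot noise of rare long binding events (arrival rate
    k_c c_c e^{-r_c Tc}/Q per unit time) filtered by the burst duration 1/r_c
    and the messenger memory 1/rA.  Intrinsic production noise is neglected
    (suppressed as 1/kA).
    """
    _, Q = _occupancy_terms(truth)
    r_c = truth.r[0]
    onrate_c = truth.on_rates[0]
    expo = np.exp(r_c * net.Tc_mean - 0.5 * r_c**2 * net.Tc_var)
    return float(Q * expo / (onrate_c * (1.0 / r_c + 1.0 / net.rA)))


@dataclass
class KPRReadout:
    """Mean readouts, saturation, both inversions and the readout noise."""

    A_mean: float
    B_mean: float
    eps: float
    c_exact: tuple[float, float]
    c_linear: tuple[float, float]
    A_relvar: float


def readout(truth: LigandMixture, net: KPRNetwork) -> KPRReadout:
    """Evaluate the full two-branch readout for a ground-truth mixture.

    eps = B/(kB/rB) is always reported so the user can judge whether the
    linearized inversion is trustworthy.
    """
    A, B = mean_readouts(truth, net)
    eps = B / (net.kB / net.rB)
    return KPRReadout(
        A_mean=A,
        B_mean=B,
        eps=float(eps),
        c_exact=invert_exact(A, B, net, truth),
        c_linear=invert_linear(A, B, net, truth),
        A_relvar=readout_relvar(truth, net),
    )
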