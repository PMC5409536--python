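"""Activator/inhibitor sequestration circuit for similar-ligand antagonism.

Two messenger branches are driven by the receptor: the activator A after a
proofreading delay Tc (production constant k_A) and the inhibitor I with no
delay (k_I).  A and I bind each other nearly irreversibly (rate r_AI),
mutually sequestering; both also degrade in first order:

    dA/dt = beta_A - rA A - rAI A I,
    dI/dt = beta_I - rI I - rAI A I.

With the matched-gain tuning k_A = k_I exp(r_nc Tc) the difference
beta_A - beta_I has a numerator independent of the non-cognate concentration,
so sequestration strips the non-cognate contribution from the A branch.  The
resulting steady state is antagonistic: with cognate ligand present, more
non-cognate ligand *lowers* A_ss (it occupies the receptor without adding to
the matched difference), while with no cognate ligand A_ss grows with the
non-cognate concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .trace_sim import LigandMixture

__all__ = [
    "SequestrationCircuit",
    "SequestrationState",
    "matched_circuit",
    "production_rates",
    "steady_state",
    "steady_state_matched",
    "quadratic_residual",
    "integrate_dynamics",
    "antagonism_curve",
]


@dataclass(frozen=True)
class SequestrationCircuit:
    """Rate constants of the A/I circuit; ``Tc`` is the extra proofreading
    delay on the A branch.  ``prefilter_Tc`` optionally models a first
    proofreading step common to both branches (off by default)."""

    kA_prod: float
    kI_prod: float
    Tc: float
    rA: float
    rI: float
    rAI: float
    prefilter_Tc: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kA_prod, self.kI_prod, self.rA, self.rI) <= 0:
            raise ValueError("production and degradation rates must be positive")
        if self.rAI < 0:
            raise ValueError("sequestration rate must be >= 0")
        if self.Tc < 0 or self.prefilter_Tc < 0:
            raise ValueError("delays must be >= 0")

    def matched_gain(self, r_nc: float, tol: float = 1e-12) -> bool:
        """Whether kA = kI exp(r_nc Tc) holds (to relative tolerance)."""
        target = self.kI_prod * np.exp(r_nc * self.Tc)
        return bool(abs(self.kA_prod - target) <= tol * target)


def matched_circuit(
    kI_prod: float,
    Tc: float,
    r_nc: float,
    rA: float,
    rI: float,
    rAI: float,
    prefilter_Tc: float = 0.0,
) -> SequestrationCircuit:
    """Build a circuit with the matched-gain tuning kA = kI exp(r_nc Tc)."""
    return SequestrationCircuit(
        kA_prod=kI_prod * float(np.exp(r_nc * Tc)),
        kI_prod=kI_prod,
        Tc=Tc,
        rA=rA,
        rI=rI,
        rAI=rAI,
        prefilter_Tc=prefilter_Tc,
    )


@dataclass
class SequestrationState:
    """Drive rates and steady-state messenger levels of the A/I circuit."""

    beta_A: float
    beta_I: float
    A_ss: float
    I_ss: float


def production_rates(
    truth: LigandMixture, circuit: SequestrationCircuit
) -> tuple[float, float]:
    """Mean production drives of the two branches:

        beta_A = sum_i (k_i c_i/r_i) e^{-r_i Tc} / Q * kA,
        beta_I = sum_i (k_i c_i/r_i)             / Q * kI,

    with Q = 1 + sum_i k_i c_i / r_i.  An optional common pre-filter delay
    multiplies each species term in both numerators by e^{-r_i Tpre}.
    """
    terms = truth.on_rates / truth.r
    Q = 1.0 + float(np.sum(terms))
    pre = np.exp(-truth.r * circuit.prefilter_Tc)
    beta_A = float(np.sum(terms * pre * np.exp(-truth.r * circuit.Tc))) / Q
    beta_I = float(np.sum(terms * pre)) / Q
    return beta_A * circuit.kA_prod, beta_I * circuit.kI_prod


def steady_state(
    beta_A: float, beta_I: float, circuit: SequestrationCircuit
) -> SequestrationState:
    """Steady state of the sequestration dynamics.

    A_ss is the positive root of the quadratic

        A^2 + (rI/rAI + (beta_I - beta_A)/rA) A - beta_A rI/(rAI rA) = 0,

    valid for any rA, rI; I_ss then follows exactly from the inhibitor
    balance I_ss = beta_I / (rI + rAI A_ss).  The discriminant is positive
    for all valid inputs.  A warning is raised when degradation is not small
    compared to sequestration (the regime where the matched-gain antagonism
    argument applies).
    """
    rA, rI, rAI = circuit.rA, circuit.rI, circuit.rAI
    if rAI == 0.0:  # decoupled linear relaxation
        return SequestrationState(
            beta_A=beta_A, beta_I=beta_I,
            A_ss=beta_A / rA, I_ss=beta_I / rI,
        )
    b = rI / (2.0 * rAI) + (beta_I - beta_A) / (2.0 * rA)
    disc = b * b + beta_A * rI / (rAI * rA)
    assert disc >= 0.0, "discriminant cannot be negative for valid inputs"
    A_ss = -b + np.sqrt(disc)
    I_ss = beta_I / (rI + rAI * A_ss)
    if A_ss > 0 and rA / (rAI * A_ss) > 0.1:
        warnings.warn(
            "degradation is not negligible against sequestration "
            "(rA/(rAI*A_ss) > 0.1); the matched-gain limit forms are "
            "approximate here",
            stacklevel=2,
        )
    return SequestrationState(
        beta_A=beta_A, beta_I=beta_I, A_ss=float(A_ss), I_ss=float(I_ss)
    )


def steady_state_matched(
    beta_A: float, beta_I: float, circuit: SequestrationCircuit
) -> tuple[float, float]:
    """Closed-form steady state in the rA = rI, degradation << sequestration
    limit:

        A_ss = (beta_A - beta_I)/(2 rI)
               + sqrt(((beta_I - beta_A)/(2 rA))^2 + beta_A/rAI),

    and symmetrically for I_ss.
    """
    if circuit.rA != circuit.rI:
        raise ValueError("limit form requires rA == rI")
    if circuit.rAI <= 0:
        raise ValueError("limit form requires sequestration (rAI > 0)")
    rI, rAI = circuit.rI, circuit.rAI
    d = (beta_A - beta_I) / (2.0 * rI)
    A_ss = d + np.sqrt(d * d + beta_A / rAI)
    I_ss = -d + np.sqrt(d * d + beta_I / rAI)
    return float(A_ss), float(I_ss)


def quadratic_residual(
    A_ss: float, beta_A: float, beta_I: float, circuit: SequestrationCircuit
) -> float:
    """Relative residual of the steady-state quadratic at A_ss."""
    rA, rI, rAI = circuit.rA, circuit.rI, circuit.rAI
    if rAI <= 0:
        raise ValueError("quadratic is defined only for rAI > 0")
    res = (
        A_ss * A_ss
        + (rI / rAI + (beta_I - beta_A) / rA) * A_ss
        - beta_A * rI / (rAI * rA)
    )
    scale = max(A_ss * A_ss, beta_A * rI / (rAI * rA), 1e-300)
    return float(abs(res) / scale)


def integrate_dynamics(
    circuit: SequestrationCircuit,
    beta_A: float,
    beta_I: float,
    t_end: float,
    initial: tuple[float, float] = (0.0, 0.0),
    rtol: float = 1e-9,
    n_points: int = 200,
) -> pd.DataFrame:
    """Integrate the coupled A/I rate equations with an implicit adaptive
    stepper (the sequestration term is stiff for large rAI).  Returns a tidy
    trajectory table with columns t, A, I."""

    def rhs(_t, y):
        A, I = y
        seq = circuit.rAI * A * I
        return [beta_A - circuit.rA * A - seq, beta_I - circuit.rI * I - seq]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        list(initial),
        method="Radau",
        rtol=rtol,
        atol=1e-12,
        t_eval=np.linspace(0.0, t_end, n_points),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return pd.DataFrame({"t": sol.t, "A": sol.y[0], "I": sol.y[1]})


def antagonism_curve(
    truth_template: LigandMixture,
    circuit: SequestrationCircuit,
    c_nc_grid,
) -> pd.DataFrame:
    """Steady-state activation versus non-cognate concentration at the fixed
    cognate concentration of ``truth_template``.

    Returns a table (c_nc, beta_A, beta_I, A_ss, I_ss).  Under matched gains
    and strong sequestration, A_ss decreases in c_nc when cognate ligand is
    present (antagonism) and increases in c_nc when it is absent.
    """
    rows = []
    c_c = truth_template.c[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c_nc in np.asarray(c_nc_grid, dtype=float):
            mix = truth_template.with_concentrations([c_c, c_nc])
            bA, bI = production_rates(mix, circuit)
            st = steady_state(bA, bI, circuit)
            rows.append(
                {
                    "c_nc": c_nc,
                    "beta_A": bA,
                    "beta_I": bI,
                    "A_ss": st.A_ss,
                    "I_ss": st.I_ss,
                }
            )
    return pd.DataFrame(rows)
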