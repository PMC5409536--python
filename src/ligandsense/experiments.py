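"""Replicated simulation studies: ML error surfaces and the fixed-cutoff
threshold-versus-ML comparison.

Grid points follow the normalization r_nc = 1, k_c = k_nc = 1,
c_c + c_nc = 1 and are indexed by the unbinding-rate ratio r_c/r_nc and the
concentration ratio c_c/c_nc.  Per point, replicate traces are simulated and
both estimators run on the *same* traces (paired design, which reduces the
variance of the reported ratios).  The default desk-scale configuration is
500 replicates of 3,000 events; the statistics reported here are means and
ratios that are converged well below the original 30,000 x 30,000 scale.

Per-replicate RNG streams are spawned from a documented counter scheme:
SeedSequence((master_seed, point_index, replicate)).
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .approx_estimator import approx_estimate, reference_cutoff
from .ml_inference import error_metrics, solve_ml
from .trace_sim import LigandMixture, sample_trace

__all__ = [
    "SweepConfig",
    "run_ml_surface",
    "run_approx_comparison",
    "report",
    "read_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    """Grid and replication settings for a simulation sweep."""

    r_ratio_grid: tuple[float, ...] = (0.05, 0.1, 0.3, 0.5, 0.7, 0.95)
    c_ratio_grid: tuple[float, ...] = (1 / 9, 1 / 3, 1.0, 3.0, 9.0)
    n_events: int = 3000
    n_replicates: int = 500
    master_seed: int = 0
    r_nc: float = 1.0
    k_c: float = 1.0
    k_nc: float = 1.0
    c_total: float = 1.0

    def __post_init__(self) -> None:
        if not self.r_ratio_grid or not self.c_ratio_grid:
            raise ValueError("grids must be nonempty")
        if self.n_events < 100:
            raise ValueError("n_events must be >= 100")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    def mixture(self, r_ratio: float, c_ratio: float) -> LigandMixture:
        c_c = self.c_total * c_ratio / (1.0 + c_ratio)
        return LigandMixture.two_species(
            k_c=self.k_c,
            r_c=r_ratio * self.r_nc,
            c_c=c_c,
            k_nc=self.k_nc,
            r_nc=self.r_nc,
            c_nc=self.c_total - c_c,
        )


def replicate_seed(master_seed: int, point: int, rep: int) -> np.random.SeedSequence:
    """The sweep's RNG counter scheme; exposed so runs can be reproduced."""
    return np.random.SeedSequence((master_seed, point, rep))


def _point_fits(config: SweepConfig, point: int, mixture: LigandMixture,
                Tc: float | None):
    """Simulate replicates at one grid point; paired ML and threshold fits."""
    mls, approxs = [], []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(replicate_seed(config.master_seed, point, rep))
        trace = sample_trace(mixture, config.n_events, rng)
        mls.append(solve_ml(trace, mixture))
        if Tc is not None:
            approxs.append(approx_estimate(trace, Tc, mixture))
    return mls, approxs


def _mse_and_se(estimates: np.ndarray, truth: float) -> tuple[float, float]:
    """Empirical loss (mean squared error against the true value) and its
    standard error over replicates."""
    sq = (estimates - truth) ** 2
    return float(sq.mean()), float(sq.std(ddof=1) / np.sqrt(len(sq)))


def run_ml_surface(config: SweepConfig) -> pd.DataFrame:
    """ML scaled errors E_c, E_nc and correlation rho over the grid."""
    rows = []
    point = 0
    for r_ratio in config.r_ratio_grid:
        for c_ratio in config.c_ratio_grid:
            mixture = config.mixture(r_ratio, c_ratio)
            mls, _ = _point_fits(config, point, mixture, None)
            em = error_metrics(mls, mixture)
            if em.n_excluded:
                log.warning(
                    "point %d (r_ratio=%g, c_ratio=%g): %d fits excluded",
                    point, r_ratio, c_ratio, em.n_excluded,
                )
            rows.append(
                {
                    "r_ratio": r_ratio,
                    "c_ratio": c_ratio,
                    "E_c": em.E_hessian[0],
                    "E_c_se": em.E_hessian_se[0],
                    "E_nc": em.E_hessian[1],
                    "E_nc_se": em.E_hessian_se[1],
                    "rho": em.rho,
                    "E_c_ensemble": em.E_ensemble[0],
                    "E_nc_ensemble": em.E_ensemble[1],
                    "n_excluded": em.n_excluded,
                }
            )
            log.info("ml surface point %d done", point)
            point += 1
    return pd.DataFrame(rows)


def run_approx_comparison(config: SweepConfig) -> pd.DataFrame:
    """Paired comparison of the fixed-cutoff threshold estimator to ML.

    Per grid point the cutoff is the fixed reference T0 (computed once per
    unbinding-rate ratio).  The empirical loss L of the threshold estimates
    (mean squared error against the truth over replicates) is divided by the
    mean inverse-Hessian variance of the paired ML fits.
    """
    rows = []
    point = 0
    for r_ratio in config.r_ratio_grid:
        probe = config.mixture(r_ratio, 1.0)
        T0 = reference_cutoff(probe, config.n_events)
        for c_ratio in config.c_ratio_grid:
            mixture = config.mixture(r_ratio, c_ratio)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mls, approxs = _point_fits(config, point, mixture, T0)
            em = error_metrics(mls, mixture)
            a = np.array([ap.c_hat_a for ap in approxs])
            L_c, L_c_se = _mse_and_se(a[:, 0], mixture.c[0])
            L_nc, L_nc_se = _mse_and_se(a[:, 1], mixture.c[1])
            var_c, var_nc = em.mean_variance
            ratio_c = L_c / var_c
            ratio_nc = L_nc / var_nc
            # relative errors of numerator and denominator in quadrature
            ml_se = em.E_hessian_se * mixture.c**2 / np.array([r.n for r in mls]).mean()
            ratio_c_se = ratio_c * np.hypot(L_c_se / L_c, ml_se[0] / var_c)
            ratio_nc_se = ratio_nc * np.hypot(L_nc_se / L_nc, ml_se[1] / var_nc)
            rho_a = float(np.corrcoef(a[:, 0], a[:, 1])[0, 1])
            rows.append(
                {
                    "r_ratio": r_ratio,
                    "c_ratio": c_ratio,
                    "T0": T0,
                    "E_c": em.E_hessian[0],
                    "E_nc": em.E_hessian[1],
                    "rho": em.rho,
                    "L_c_T0": L_c,
                    "L_c_T0_se": L_c_se,
                    "L_nc_T0": L_nc,
                    "L_nc_T0_se": L_nc_se,
                    "ratio_c": ratio_c,
                    "ratio_c_se": ratio_c_se,
                    "ratio_nc": ratio_nc,
                    "ratio_nc_se": ratio_nc_se,
                    "rho_a": rho_a,
                    "n_excluded": em.n_excluded,
                }
            )
            log.info("comparison point %d done", point)
            point += 1
    return pd.DataFrame(rows)


def report(table: pd.DataFrame, path, config: SweepConfig | None = None,
           fmt: str = "tsv") -> None:
    """Write a sweep table with a provenance block (config, seed, version).

    TSV output carries the provenance as leading '# key=value' comment
    lines; JSON output nests it under a "provenance" key.  Bit-reproducible
    given identical config and master seed.
    """
    prov = {"version": __version__}
    if config is not None:
        prov.update(asdict(config))
    if fmt == "tsv":
        with open(path, "w") as fh:
            for key, val in prov.items():
                fh.write(f"# {key}={json.dumps(val)}\n")
            table.to_csv(fh, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(
                {"provenance": prov, "rows": table.to_dict(orient="records")},
                fh,
                indent=1,
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_report(path, fmt: str = "tsv") -> tuple[pd.DataFrame, dict]:
    """Read a report written by :func:`report`; returns (table, provenance)."""
    if fmt == "tsv":
        prov = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("# "):
                break
            key, _, val = line[2:].rstrip("\n").partition("=")
            prov[key] = json.loads(val)
            body_start += 1
        from io import StringIO

        table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        return table, prov
    if fmt == "json":
        with open(path) as fh:
            obj = json.load(fh)
        return pd.DataFrame(obj["rows"]), obj["provenance"]
    raise ValueError(f"unknown format {fmt!r}")
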