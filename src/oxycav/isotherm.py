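"""Single-site fast-exchange binding isotherm and its global fit.

Under fast exchange the observed chemical-shift change of a nucleus at
dissolved-ligand concentration ``[L]`` is a population-weighted average,

    dd([L]) = dd_max * K [L] / (1 + K [L]),

with one association constant ``K`` (M^-1) shared by every nucleus and a
nucleus-specific saturation shift ``dd_max`` (ppm).  Concentrations are
carried in mM (the natural scale for dissolved O2) and converted to M
inside the model so that ``K`` comes out in M^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "IsothermFit",
    "FitError",
    "bound_fraction",
    "predict_shift",
    "global_fit",
    "dissociation_constant",
    "read_titration_table",
]


class FitError(Exception):
    """Raised when a titration fit cannot be carried out or fails to converge."""


@dataclass
class TitrationSeries:
    """Chemical-shift changes of one nucleus across ligand concentrations.

    ``concentrations`` are mM of dissolved ligand, strictly increasing;
    ``shifts`` are ppm relative to the lowest concentration.
    """

    nucleus_label: str
    concentrations: np.ndarray  # mM
    shifts: np.ndarray  # ppm

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.shifts, dtype=float)
        if c.shape != s.shape or c.ndim != 1:
            raise ValueError(f"{self.nucleus_label}: concentrations and shifts must match 1-D")
        if (c < 0).any():
            raise ValueError(f"{self.nucleus_label}: negative concentration")
        if (np.diff(c) <= 0).any():
            raise ValueError(f"{self.nucleus_label}: concentrations must be strictly increasing")
        self.concentrations = c
        self.shifts = s

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class IsothermFit:
    """Result of the global shared-K fit."""

    K: float  # association constant, M^-1
    K_se: float  # standard error, M^-1
    ddmax: dict[str, float]  # per-series saturation shift, ppm
    ddmax_se: dict[str, float]  # ppm
    residual_rms: float  # ppm
    n_points: int
    n_iterations: int

    @property
    def Kd_mM(self) -> float:
        return dissociation_constant(self.K)

    def report(self) -> pd.DataFrame:
        rows = [("K_per_M", self.K, self.K_se), ("Kd_mM", self.Kd_mM, 1000.0 * self.K_se / self.K**2)]
        rows += [(f"ddmax_ppm[{k}]", v, self.ddmax_se[k]) for k, v in self.ddmax.items()]
        rows.append(("residual_rms_ppm", self.residual_rms, np.nan))
        return pd.DataFrame(rows, columns=["parameter", "value", "stderr"])


def bound_fraction(K: float, conc_mM: float | np.ndarray) -> float | np.ndarray:
    """Fraction of protein in the ligand-bound state, ``K[L]/(1+K[L])``.

    ``K`` in M^-1, ``conc_mM`` in mM (converted to M internally).
    """
    if K <= 0:
        raise ValueError(f"association constant must be positive, got {K}")
    conc = np.asarray(conc_mM, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentration must be non-negative")
    c_M = conc * 1e-3
    out = K * c_M / (1.0 + K * c_M)
    return float(out) if out.ndim == 0 else out


def predict_shift(K: float, ddmax: float, conc_mM: float | np.ndarray) -> float | np.ndarray:
    """Predicted shift change (ppm): ``ddmax * bound_fraction(K, conc)``."""
    return ddmax * bound_fraction(K, conc_mM)


def dissociation_constant(K: float) -> float:
    """Dissociation constant in mM: reciprocal of ``K`` (M^-1)."""
    if K <= 0:
        raise ValueError(f"association constant must be positive, got {K}")
    return 1000.0 / K


def global_fit(
    series: Sequence[TitrationSeries],
    weights: Sequence[float] | None = None,
    use_magnitudes: bool = False,
) -> IsothermFit:
    """Least-squares fit of all titration series with one shared ``K``.

    Minimises the summed squared residuals over every point of every
    series, with ``K`` parameterised as ``exp(theta)`` to enforce
    positivity (start: ``K0 = 1/median concentration``).  Standard errors
    come from the Gauss–Newton curvature at the optimum.  ``weights`` are
    optional per-series multipliers on the residuals (default: unweighted
    ppm across nuclei).
    """
    if len(series) == 0:
        raise FitError("global_fit needs at least one titration series")
    for s in series:
        if len(s) < 2:
            raise FitError(f"{s.nucleus_label}: need >=2 titration points, got {len(s)}")
    n_total = sum(len(s) for s in series)
    if n_total < 1 + len(series):
        raise FitError("underdetermined fit: fewer points than parameters")
    all_conc = np.concatenate([s.concentrations for s in series])
    if len(np.unique(all_conc)) < 2:
        raise FitError("need at least 2 distinct concentrations to fit an isotherm")
    if weights is None:
        w = np.ones(len(series))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(series),) or (w <= 0).any():
            raise FitError("weights must be positive, one per series")

    conc = [s.concentrations for s in series]
    obs = [np.abs(s.shifts) if use_magnitudes else s.shifts for s in series]

    def residuals(params: np.ndarray) -> np.ndarray:
        K = np.exp(params[0])
        out = []
        for i, (c, y) in enumerate(zip(conc, obs)):
            out.append(w[i] * (params[1 + i] * bound_fraction(K, c) - y))
        return np.concatenate(out)

    K0 = 1.0 / (np.median(all_conc) * 1e-3)
    # start ddmax at the last-point shift extrapolated by the K0 occupancy
    x0 = [np.log(K0)]
    for c, y in zip(conc, obs):
        f_last = bound_fraction(K0, c[-1])
        x0.append(y[-1] / f_last if f_last > 0 else 0.0)
    sol = least_squares(residuals, np.asarray(x0), method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError(f"global isotherm fit did not converge: {sol.message} "
                       f"(nfev={sol.nfev}, cost={sol.cost:.3g})")

    n = sum(len(s) for s in series)
    p = 1 + len(series)
    dof = max(n - p, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    K = float(np.exp(sol.x[0]))
    K_se = float(K * se[0])  # delta method through exp
    ddmax = {s.nucleus_label: float(sol.x[1 + i]) for i, s in enumerate(series)}
    ddmax_se = {s.nucleus_label: float(se[1 + i]) for i, s in enumerate(series)}
    rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
    return IsothermFit(K, K_se, ddmax, ddmax_se, rms, n_points=n, n_iterations=int(sol.nfev))


def read_titration_table(path: str | Path) -> list[TitrationSeries]:
    """Read titration data from a table with columns
    ``nucleus_label, conc_mM, delta_ppm`` (tab- or comma-separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"nucleus_label", "conc_mM", "delta_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration table needs columns {sorted(required)}, got {list(df.columns)}")
    out = []
    for label, grp in df.groupby("nucleus_label", sort=False):
        grp = grp.sort_values("conc_mM")
        out.append(TitrationSeries(str(label), grp["conc_mM"].to_numpy(), grp["delta_ppm"].to_numpy()))
    return out
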