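"""Multi-site 1/r^6 paramagnetic relaxation enhancement (PRE) model.

The longitudinal relaxation enhancement of proton ``p`` caused by a
paramagnetic ligand occupying ``n`` discrete sites is modelled as

    dR1(p) = sum_i  c_i * 1e5 * r_i(p)^-6  +  f,

where ``r_i`` is the proton–site distance in Å, ``c_i`` (site
coefficients, in units of 1e5 Å^6/s) are proportional to ligand
occupancy at each site, and ``f`` (s^-1) is a distance-independent
baseline from surface-diffusing ligand and spin diffusion.  The 1e5
scale keeps fitted coefficients of order one.

Coefficients are fitted by non-negative least squares: occupancies
cannot be negative, and exact zeros signal sites the data do not
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .structures import DistanceTable, SiteGeometry

__all__ = [
    "SCALE",
    "PREObservation",
    "PREFitResult",
    "SiteContribution",
    "predict_dr1",
    "fit_pre",
    "site_contributions",
    "occupancy_ratio",
    "binding_probability",
    "broadening_screen",
    "read_pre_table",
]

#: Model scale factor applied to every site coefficient (Å^6/s per printed unit).
SCALE = 1e5


@dataclass
class PREObservation:
    """One observed relaxation enhancement, optionally excluded from fitting."""

    proton_label: str
    dR1: float  # s^-1
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.excluded and not np.isfinite(self.dR1):
            raise ValueError(f"{self.proton_label}: non-finite dR1 in a non-excluded observation")


@dataclass
class PREFitResult:
    """Fitted site coefficients and goodness of fit.

    ``coefficients`` are in the printed unit convention (multiply by 1e5
    Å^6/s inside the model); ``baseline`` is in s^-1.
    """

    coefficients: np.ndarray  # (n_sites,), >= 0
    baseline: float  # f, s^-1, >= 0
    r_squared: float
    see: float  # standard error of the estimate, s^-1
    n_used: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if (c < 0).any() or self.baseline < 0:
            raise ValueError("site coefficients and baseline must be non-negative")
        self.coefficients = c

    def report(self) -> pd.DataFrame:
        names = [chr(ord("a") + i) for i in range(len(self.coefficients))]
        rows = [(n, v) for n, v in zip(names, self.coefficients)]
        rows += [("f", self.baseline), ("r_squared", self.r_squared),
                 ("see", self.see), ("n_used", self.n_used)]
        return pd.DataFrame(rows, columns=["parameter", "value"])


@dataclass
class SiteContribution:
    """Per-proton decomposition of predicted dR1 into site shares plus baseline."""

    shares: pd.DataFrame  # rows × sites, s^-1
    baseline: float  # s^-1

    @property
    def predicted(self) -> pd.Series:
        return self.shares.sum(axis=1) + self.baseline


def predict_dr1(fit: PREFitResult | np.ndarray, table: DistanceTable,
                baseline: float | None = None) -> pd.Series:
    """Predicted dR1 (s^-1) per table row.

    ``fit`` may be a :class:`PREFitResult` or a bare coefficient vector
    (then ``baseline`` must be given).
    """
    if isinstance(fit, PREFitResult):
        coeffs, f = fit.coefficients, fit.baseline
    else:
        coeffs = np.asarray(fit, dtype=float)
        if baseline is None:
            raise ValueError("baseline required when passing bare coefficients")
        f = float(baseline)
    if len(coeffs) != table.n_sites:
        raise ValueError(
            f"coefficient count {len(coeffs)} does not match {table.n_sites} sites"
        )
    vals = table.matrix @ (coeffs * SCALE) + f
    return pd.Series(vals, index=table.labels, name="dR1_pred")


def fit_pre(obs: Sequence[PREObservation], table: DistanceTable) -> PREFitResult:
    """Fit the multi-site model to observed dR1 by non-negative least squares.

    Excluded observations never enter the objective (they still receive
    predictions downstream).  ``r_squared`` is the squared Pearson
    correlation of observed versus predicted over the fitted points and
    ``see`` the root-mean-squared prediction residual.
    """
    label_set = set(table.labels)
    missing = [o.proton_label for o in obs if o.proton_label not in label_set]
    if missing:
        raise ValueError(f"observations without distance-table rows: {missing}")
    used = [o for o in obs if not o.excluded]
    if not used:
        raise ValueError("all observations are excluded; nothing to fit")
    n_par = table.n_sites + 1
    if len(used) < n_par + 1:
        raise ValueError(
            f"underdetermined PRE fit: {len(used)} usable observations for {n_par} parameters"
        )
    rows = [table.labels.index(o.proton_label) for o in used]
    A = np.hstack([table.matrix[rows] * SCALE, np.ones((len(rows), 1))])
    y = np.array([o.dR1 for o in used], dtype=float)
    coef, _ = nnls(A, y)
    # snap numerically-null coefficients to exact zero (active constraint)
    tol = 1e-10 * max(coef.max(), 1.0)
    coef[coef < tol] = 0.0
    pred = A @ coef
    resid = y - pred
    see = float(np.sqrt(np.mean(resid**2)))
    if np.std(y) == 0 or np.std(pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, pred)[0, 1] ** 2)
    return PREFitResult(
        coefficients=coef[:-1],
        baseline=float(coef[-1]),
        r_squared=r2,
        see=see,
        n_used=len(used),
    )


def site_contributions(fit: PREFitResult, table: DistanceTable) -> SiteContribution:
    """Decompose each predicted dR1 into per-site shares.

    Site ``i``'s share for a proton is ``(pred - f) * t_i / sum_j t_j``
    with ``t_i = c_i * 1e5 / r_i^6``; shares plus the baseline reconstruct
    the prediction exactly.  A proton with all site terms zero is
    baseline-only (all shares zero).
    """
    terms = table.matrix * (fit.coefficients * SCALE)[None, :]
    total = terms.sum(axis=1)
    pred = total + fit.baseline
    shares = np.zeros_like(terms)
    nz = total > 0
    shares[nz] = (pred[nz] - fit.baseline)[:, None] * terms[nz] / total[nz, None]
    df = pd.DataFrame(shares, index=table.labels,
                      columns=[f"site_{s}" for s in table.site_ids])
    return SiteContribution(shares=df, baseline=fit.baseline)


def occupancy_ratio(fit: PREFitResult, sites: SiteGeometry,
                    cavity_a: int, cavity_b: int) -> float:
    """Relative ligand occupancy of ``cavity_a`` versus ``cavity_b``.

    Site coefficients are occupancy-proportional, so the ratio of their
    per-cavity sums estimates the relative occupancy.
    """
    cav = sites.cavities
    if cavity_a not in cav or cavity_b not in cav:
        raise ValueError(f"cavity labels {cavity_a}/{cavity_b} not both present in geometry")
    num = fit.coefficients[cav == cavity_a].sum()
    den = fit.coefficients[cav == cavity_b].sum()
    if den == 0:
        raise ValueError(f"cavity {cavity_b} has zero total coefficient; ratio undefined")
    return float(num / den)


def binding_probability(dr1_obs: float, contact_rate: float = 6200.0) -> float:
    """Upper-bound binding probability from an observed dR1.

    Normalises against the relaxation rate of a proton in permanent van
    der Waals contact with the paramagnet (~6200 s^-1 for O2), so the
    result is the occupancy that would produce the observed enhancement
    if the ligand sat at contact distance whenever bound.
    """
    if dr1_obs < 0:
        raise ValueError(f"dR1 must be non-negative, got {dr1_obs}")
    if contact_rate <= 0:
        raise ValueError(f"contact rate must be positive, got {contact_rate}")
    return dr1_obs / contact_rate


def broadening_screen(table: DistanceTable, threshold: float = 6.0) -> pd.Series:
    """Flag rows whose minimum raw proton–site distance is strictly below
    ``threshold`` (Å): these are candidates for severe PRE line broadening."""
    return (table.r_min_raw < threshold).rename("broadening_risk")


def read_pre_table(path: str | Path) -> list[PREObservation]:
    """Read observations from a table with columns
    ``proton_label, dR1_s, excluded, reason`` (tab- or comma-separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"proton_label", "dR1_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"PRE table needs columns {sorted(required)}, got {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        excluded = bool(row["excluded"]) if "excluded" in df.columns and not pd.isna(row.get("excluded")) else False
        reason = str(row["reason"]) if "reason" in df.columns and not pd.isna(row.get("reason")) else ""
        dr1 = row["dR1_s"]
        out.append(PREObservation(str(row["proton_label"]),
                                  float(dr1) if not pd.isna(dr1) else np.nan,
                                  excluded, reason))
    return out
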