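"""Ligand-trajectory analysis: occupancy density, cavity events, rotation.

Works on plain tabular time series in the protein-fixed frame:
positions of the ligand centre (Å) or unit bond-direction vectors.
Three analyses are provided:

* a voxelised 3-D occupancy density with hotspot extraction (voxels
  whose count exceeds a multiple of the mean occupied-voxel count);
* per-frame cavity assignment by proximity to paramagnet sites, with
  binding / egress / transition event detection;
* rank-1/rank-2 orientational autocorrelation and single- versus
  bi-exponential decay fitting, yielding rotational correlation times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .structures import SiteGeometry

__all__ = [
    "PositionTrajectory",
    "OrientationTrajectory",
    "DensityGrid",
    "CavityEvent",
    "CavityAssignment",
    "ACFFit",
    "density_grid",
    "hotspots",
    "assign_cavity",
    "orientation_acf",
    "fit_acf",
    "read_trajectory_table",
]

OUTSIDE = "outside"


@dataclass
class PositionTrajectory:
    """Ligand-centre positions (Å), one frame every ``dt`` ps."""

    dt: float  # ps
    frames: np.ndarray  # (n, 3) Å

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 2:
            raise ValueError("frames must be an (n>=2, 3) array")
        self.frames = f

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.dt


@dataclass
class OrientationTrajectory:
    """Unit bond-direction vectors in the protein frame, every ``dt`` ps."""

    dt: float  # ps
    frames: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 2:
            raise ValueError("frames must be an (n>=2, 3) array")
        norms = np.linalg.norm(f, axis=1)
        if np.abs(norms - 1.0).max() > 1e-6:
            raise ValueError("orientation frames must be unit vectors (|norm-1| <= 1e-6)")
        self.frames = f

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DensityGrid:
    """Voxel counts of ligand positions over a padded bounding box."""

    origin: np.ndarray  # (3,) Å
    voxel: float  # Å
    counts: np.ndarray  # (nx, ny, nz) int

    def __post_init__(self) -> None:
        if self.voxel <= 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel}")
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())

    def to_table(self) -> pd.DataFrame:
        """Occupied voxels as an (i, j, k, count) table."""
        idx = np.argwhere(self.counts > 0)
        return pd.DataFrame(
            {"i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
             "count": self.counts[idx[:, 0], idx[:, 1], idx[:, 2]]}
        )

    def export(self, path: str | Path) -> None:
        """Write a volumetric text header plus the occupied-voxel table."""
        with open(path, "w") as fh:
            fh.write(f"# origin\t{self.origin[0]:.6g}\t{self.origin[1]:.6g}\t{self.origin[2]:.6g}\n")
            fh.write(f"# voxel\t{self.voxel:.6g}\n")
            fh.write(f"# dims\t{self.counts.shape[0]}\t{self.counts.shape[1]}\t{self.counts.shape[2]}\n")
            self.to_table().to_csv(fh, sep="\t", index=False)


def density_grid(traj: PositionTrajectory, voxel: float) -> DensityGrid:
    """Bin trajectory frames into cubic voxels.

    The grid covers the bounding box of the trajectory padded by one
    voxel on every side; every frame lands in exactly one voxel.
    """
    if voxel <= 0:
        raise ValueError(f"voxel size must be positive, got {voxel}")
    pos = traj.frames
    lo = pos.min(axis=0) - voxel
    hi = pos.max(axis=0) + voxel
    dims = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    idx = np.floor((pos - lo) / voxel).astype(int)
    idx = np.clip(idx, 0, dims - 1)  # points exactly on the upper face
    counts = np.zeros(dims, dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return DensityGrid(origin=lo, voxel=voxel, counts=counts)


def hotspots(grid: DensityGrid, factor: float = 4.0,
             occupied_only: bool = True) -> set[tuple[int, int, int]]:
    """Voxels whose count exceeds ``factor`` times the mean count.

    By default the mean is taken over occupied voxels (count > 0), so
    the result does not depend on how much empty padding surrounds the
    sampled region; ``occupied_only=False`` averages over the whole box.
    """
    counts = grid.counts
    if occupied_only:
        occ = counts[counts > 0]
        if occ.size == 0:
            return set()
        mean = occ.mean()
    else:
        mean = counts.mean()
    sel = np.argwhere(counts > factor * mean)
    return {tuple(int(v) for v in row) for row in sel}


# ---------------------------------------------------------------------------
# Cavity assignment and events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavityEvent:
    kind: Literal["binding", "rebinding", "egress", "transition"]
    frame: int
    time_ps: float
    from_label: int | str
    to_label: int | str


@dataclass
class CavityAssignment:
    labels: list[int | str]  # per frame: cavity id or "outside"
    events: list[CavityEvent]

    def occupancy(self) -> pd.Series:
        return pd.Series(self.labels).value_counts(normalize=True)


def _runs(labels: Sequence) -> list[tuple[object, int, int]]:
    """Run-length encode: (label, start, length)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return runs


def assign_cavity(
    traj: PositionTrajectory,
    sites: SiteGeometry,
    cutoff: float = 5.0,
    debounce_ps: float = 0.0,
) -> CavityAssignment:
    """Label each frame with the cavity of the nearest site (within
    ``cutoff`` Å) or ``"outside"``, and detect label-change events.

    Runs shorter than ``debounce_ps`` are absorbed into the preceding
    run before event extraction, suppressing single-frame flicker; with
    the default 0 every raw change is an event.  Egress = cavity to
    outside; binding/rebinding = outside to cavity (rebinding once any
    cavity has been visited before); transition = cavity to cavity.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    diff = traj.frames[:, None, :] - sites.positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    nearest = dist.argmin(axis=1)
    mind = dist.min(axis=1)
    cav = sites.cavities
    labels: list[int | str] = [
        int(cav[nearest[i]]) if mind[i] <= cutoff else OUTSIDE for i in range(len(traj))
    ]

    min_dwell = int(round(debounce_ps / traj.dt)) if debounce_ps > 0 else 0
    runs = _runs(labels)
    if min_dwell > 1:
        merged: list[list] = []
        for lab, start, length in runs:
            if merged and (length < min_dwell or lab == merged[-1][0]):
                merged[-1][2] += length
            elif not merged and length < min_dwell:
                merged.append([lab, start, length])  # provisional head run
            else:
                merged.append([lab, start, length])
        # a short head run is absorbed into the following run's label
        if len(merged) > 1 and merged[0][2] < min_dwell:
            merged[1][1] = merged[0][1]
            merged[1][2] += merged[0][2]
            merged.pop(0)
        runs = [tuple(m) for m in merged]

    events: list[CavityEvent] = []
    visited_cavity = runs[0][0] != OUTSIDE if runs else False
    for prev, cur in zip(runs, runs[1:]):
        a, b = prev[0], cur[0]
        frame = cur[1]
        if a == b:
            continue
        if a != OUTSIDE and b != OUTSIDE:
            kind = "transition"
        elif a != OUTSIDE and b == OUTSIDE:
            kind = "egress"
        else:
            kind = "rebinding" if visited_cavity else "binding"
        if b != OUTSIDE:
            visited_cavity = True
        events.append(CavityEvent(kind, frame, frame * traj.dt, a, b))
    smoothed = []
    for lab, start, length in runs:
        smoothed.extend([lab] * length)
    return CavityAssignment(labels=smoothed, events=events)


# ---------------------------------------------------------------------------
# Orientational autocorrelation
# ---------------------------------------------------------------------------

def orientation_acf(
    traj: OrientationTrajectory,
    max_lag_ps: float,
    rank: int = 2,
) -> pd.DataFrame:
    """Rank-``l`` orientational autocorrelation curve.

    ``C_l(tau) = < P_l(u(t) . u(t+tau)) >`` averaged over all t (the
    n - lag overlapping origins), with ``C_l(0) = 1`` by unit norm.
    Rank 2 (the default) is the order governing dipolar relaxation.
    """
    if rank not in (1, 2):
        raise ValueError(f"rank must be 1 or 2, got {rank}")
    n = len(traj)
    max_lag = int(np.floor(max_lag_ps / traj.dt))
    if max_lag >= n:
        raise ValueError(
            f"max_lag {max_lag_ps} ps spans >= the trajectory ({(n - 1) * traj.dt} ps)"
        )
    u = traj.frames
    lags = np.arange(max_lag + 1)
    vals = np.empty(max_lag + 1)
    for k in lags:
        dots = (u[: n - k] * u[k:]).sum(axis=1) if k else np.ones(n)
        if rank == 1:
            vals[k] = dots.mean()
        else:
            vals[k] = (1.5 * dots**2 - 0.5).mean()
    return pd.DataFrame({"lag_ps": lags * traj.dt, "acf": vals})


@dataclass
class ACFFit:
    """Exponential-decay fit of an orientational ACF curve.

    For a bi-exponential, ``C(t) = A exp(-t/tau_fast) + (1-A) exp(-t/tau_slow)``
    with ``A`` in [0, 1] and ``tau_fast <= tau_slow``; a single
    exponential has ``A = 1`` and ``tau_fast = tau_slow``.
    """

    model: Literal["single", "biexponential"]
    amplitude: float  # A, fraction on the fast component
    tau_fast: float  # ps
    tau_slow: float  # ps
    sse: float
    model_preference: dict

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError(f"amplitude must lie in [0, 1], got {self.amplitude}")
        if not (0 < self.tau_fast <= self.tau_slow):
            raise ValueError(
                f"need 0 < tau_fast <= tau_slow, got {self.tau_fast}, {self.tau_slow}"
            )

    def predict(self, t: np.ndarray) -> np.ndarray:
        return (self.amplitude * np.exp(-np.asarray(t) / self.tau_fast)
                + (1.0 - self.amplitude) * np.exp(-np.asarray(t) / self.tau_slow))


class ACFFitError(Exception):
    """Raised when exponential fitting of an ACF curve fails."""


def _as_curve(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, pd.DataFrame):
        return curve["lag_ps"].to_numpy(float), curve["acf"].to_numpy(float)
    t, c = curve
    return np.asarray(t, dtype=float), np.asarray(c, dtype=float)


def _fit_single(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Fit C(t)=exp(-t/tau); returns (tau, sse)."""
    pos = (c > 1e-12) & (t > 0)
    if pos.sum() >= 2:
        tau0 = float(np.clip(-1.0 / np.polyfit(t[pos], np.log(c[pos]), 1)[0], 1e-6, None))
    else:
        tau0 = max(t[1] - t[0], 1e-3)

    def resid(x):
        return np.exp(-t / np.exp(x[0])) - c

    sol = least_squares(resid, [np.log(tau0)], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise ACFFitError(f"single-exponential fit failed: {sol.message}")
    return float(np.exp(sol.x[0])), float(2.0 * sol.cost)


def _fit_biexp(t: np.ndarray, c: np.ndarray,
               starts: list[tuple[float, float, float]]) -> tuple[float, float, float, float]:
    """Fit the constrained bi-exponential from several starts; best SSE wins.

    Returns (A, tau_fast, tau_slow, sse)."""

    def resid(x):
        A = x[0]
        return (A * np.exp(-t / np.exp(x[1])) + (1 - A) * np.exp(-t / np.exp(x[2])) - c)

    best = None
    for A0, tf0, ts0 in starts:
        sol = least_squares(
            resid,
            [A0, np.log(tf0), np.log(ts0)],
            bounds=([0.0, -30.0, -30.0], [1.0, 30.0, 30.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise ACFFitError("bi-exponential fit failed to converge")
    A = float(best.x[0])
    tf, ts = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    if tf > ts:
        tf, ts, A = ts, tf, 1.0 - A
    return A, tf, ts, float(2.0 * best.cost)


def fit_acf(curve, model: str = "biexponential") -> ACFFit:
    """Fit a single- or bi-exponential decay to an ACF curve.

    ``curve`` is the DataFrame from :func:`orientation_acf` or a
    ``(lags_ps, values)`` pair.  Both models are always fitted so the
    result carries a model-preference record (their SSEs); the returned
    parameters are those of the requested ``model``.
    """
    if model not in ("single", "biexponential"):
        raise ValueError(f"unknown ACF model: {model!r}")
    t, c = _as_curve(curve)
    min_pts = 5 if model == "single" else 7
    if len(t) < min_pts:
        raise ValueError(f"{model} fit needs >= {min_pts} lags, got {len(t)}")

    tau1, sse1 = _fit_single(t, c)
    starts = [
        (0.5, max(tau1 / 10.0, 1e-6), tau1),
        (0.5, tau1, tau1 * (1 + 1e-6)),  # degenerate start at the single solution
        (0.3, max(tau1 / 30.0, 1e-6), tau1 * 3.0),
    ]
    A, tf, ts, sse2 = _fit_biexp(t, c, starts)
    if sse2 > sse1:  # nested model: never worse than its special case
        A, tf, ts, sse2 = 1.0, tau1, tau1, sse1
    pref = {
        "single_sse": sse1,
        "biexponential_sse": sse2,
        "preferred": "biexponential" if sse2 < sse1 else "single",
    }
    if model == "single":
        return ACFFit("single", 1.0, tau1, tau1, sse1, pref)
    return ACFFit("biexponential", A, tf, ts, sse2, pref)


def read_trajectory_table(path: str | Path, kind: str = "position"):
    """Read a plain trajectory table ``t_ps, x, y, z`` (positions, Å) or
    ``t_ps, ux, uy, uz`` (unit vectors); tab- or comma-separated."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] != 4:
        raise ValueError(f"trajectory table needs 4 columns, got {df.shape[1]}")
    t = df.iloc[:, 0].to_numpy(float)
    xyz = df.iloc[:, 1:4].to_numpy(float)
    if len(t) < 2:
        raise ValueError("trajectory needs >= 2 frames")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trajectory must be uniformly sampled in time")
    if kind == "position":
        return PositionTrajectory(dt=float(dts[0]), frames=xyz)
    if kind == "orientation":
        return OrientationTrajectory(dt=float(dts[0]), frames=xyz)
    raise ValueError(f"unknown trajectory kind: {kind!r}")
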