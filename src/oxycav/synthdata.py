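"""Synthetic-data generators with embedded ground truth.

Every generator is a pure function of its parameters and a seed:
identical calls give identical output, and each result carries a
``meta`` dictionary echoing the parameters and the true values used, so
downstream recovery tests read truth from metadata rather than
hard-coding numbers.

Default parameter choices mirror the study conditions of O2 binding to
T4 lysozyme L99A: a five-point dissolved-O2 concentration grid from
atmospheric (0.27 mM) up to 8.9 mM, an association constant of
48 M^-1, five paramagnet sites split between two hydrophobic cavities,
and the fitted per-site PRE coefficients for amide and methyl protons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .isotherm import TitrationSeries, predict_shift
from .premodel import SCALE, PREObservation, predict_dr1
from .structures import (
    DistanceTable,
    Proton,
    ProtonSet,
    Site,
    SiteGeometry,
    distance_table,
)
from .trajmd import OrientationTrajectory, PositionTrajectory

__all__ = [
    "DEFAULT_CONCS_MM",
    "DEFAULT_K",
    "DEFAULT_DDMAX",
    "AMIDE_COEFFS",
    "AMIDE_BASELINE",
    "AMIDE_SEE",
    "METHYL_COEFFS",
    "METHYL_BASELINE",
    "METHYL_SEE",
    "default_sites",
    "gen_titration",
    "gen_geometry",
    "gen_pre_field",
    "gen_position_traj",
    "gen_scripted_traj",
    "gen_orientation_traj",
    "gen_acf_curve",
    "gen_structure_fixture",
]

# --- study conditions -------------------------------------------------------

#: Dissolved-O2 concentration grid, mM (atmospheric up to ~7 bar).
DEFAULT_CONCS_MM: tuple[float, ...] = (0.27, 1.8, 3.8, 6.4, 8.9)

#: Association constant of the O2/L99A single-site isotherm, M^-1.
DEFAULT_K: float = 48.0

#: Saturation shifts (ppm) of the nuclei tracked through the titration.
DEFAULT_DDMAX: dict[str, float] = {
    "K85 N": 0.8,
    "Y88 N": 5.3,
    "D89 N": 0.5,
    "A99 N": 2.1,
    "I100 N": 0.6,
    "L118 N": 0.8,
    "I78 Hd1": 0.39,
    "I78 Hg2": 0.32,
    "M102 He": 0.61,
    "I78 Cd1": 2.3,
    "I78 Cg2": 2.7,
    "M102 Ce": 3.9,
}

#: Shift-noise defaults by nucleus type, ppm (1H is read more precisely).
NOISE_BY_NUCLEUS: dict[str, float] = {"H": 0.01, "N": 0.05, "C": 0.05}

#: Fitted per-site PRE coefficients (x 1e5 Å^6/s) and baselines (s^-1).
AMIDE_COEFFS: tuple[float, ...] = (1.3, 1.1, 1.5, 0.11, 0.10)
AMIDE_BASELINE: float = 1.1
AMIDE_SEE: float = 0.74
METHYL_COEFFS: tuple[float, ...] = (1.8, 0.0, 3.1, 0.0, 0.046)
METHYL_BASELINE: float = 0.79
METHYL_SEE: float = 3.0


def default_sites(spacing: float = 8.0) -> SiteGeometry:
    """Five paramagnet sites: 1–3 in cavity 4, 4–5 in cavity 3.

    Synthetic stand-in coordinates (not the crystallographic ones):
    sites are laid out on two well-separated clusters ``spacing`` Å
    apart so the 1/r^6 design is generically full-rank.
    """
    return SiteGeometry(
        [
            Site(1, np.array([0.0, 0.0, 0.0]), 4),
            Site(2, np.array([spacing * 0.5, 0.0, 0.0]), 4),
            Site(3, np.array([0.0, spacing * 0.5, 0.0]), 4),
            Site(4, np.array([3 * spacing, 0.0, 0.0]), 3),
            Site(5, np.array([3 * spacing, spacing * 0.5, 0.0]), 3),
        ]
    )


def _nucleus_kind(label: str) -> str:
    """Last alphabetic token's leading letter: 'A99 N' -> N, 'I78 Hd1' -> H."""
    token = label.split()[-1]
    return token[0].upper()


# --- titration --------------------------------------------------------------

@dataclass
class TitrationData:
    series: list[TitrationSeries]
    meta: dict


def gen_titration(
    K: float = DEFAULT_K,
    ddmax_table: Mapping[str, float] | None = None,
    concs_mM: Sequence[float] = DEFAULT_CONCS_MM,
    noise_sd: float | Mapping[str, float] | None = None,
    seed: int = 0,
) -> TitrationData:
    """Titration series from the single-site isotherm plus Gaussian noise.

    ``noise_sd`` may be a single ppm value, a per-label mapping, or
    ``None`` for the per-nucleus-type defaults (0.01 ppm for 1H,
    0.05 ppm for 15N/13C).  Noise 0 gives the exact model curves.
    """
    if len(concs_mM) == 0:
        raise ValueError("empty concentration grid")
    if ddmax_table is None:
        ddmax_table = DEFAULT_DDMAX
    rng = np.random.default_rng(seed)
    concs = np.asarray(concs_mM, dtype=float)
    series: list[TitrationSeries] = []
    noise_used: dict[str, float] = {}
    for label, ddmax in ddmax_table.items():
        if noise_sd is None:
            sd = NOISE_BY_NUCLEUS.get(_nucleus_kind(label), 0.05)
        elif isinstance(noise_sd, Mapping):
            sd = float(noise_sd[label])
        else:
            sd = float(noise_sd)
        if sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {sd}")
        noise_used[label] = sd
        shifts = predict_shift(K, ddmax, concs)
        if sd > 0:
            shifts = shifts + rng.normal(0.0, sd, size=len(concs))
        series.append(TitrationSeries(label, concs, np.asarray(shifts)))
    meta = {
        "kind": "titration",
        "seed": seed,
        "K_true": K,
        "ddmax_true": dict(ddmax_table),
        "concs_mM": list(concs),
        "noise_sd": noise_used,
    }
    return TitrationData(series=series, meta=meta)


# --- geometry ---------------------------------------------------------------

@dataclass
class GeometryData:
    protons: ProtonSet
    table: DistanceTable
    sites: SiteGeometry
    meta: dict


def gen_geometry(
    n_protons: int = 50,
    sites: SiteGeometry | None = None,
    r_range: tuple[float, float] = (3.0, 20.0),
    seed: int = 0,
) -> GeometryData:
    """Protons on random shells around randomly chosen sites.

    Each proton is placed at a uniform-random radius in ``r_range``
    around a uniformly chosen site, in a uniform-random direction,
    which yields a generic (full-column-rank) 1/r^6 design matrix for
    coefficient fitting.
    """
    if n_protons < 1:
        raise ValueError("need at least one proton")
    lo, hi = r_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid radius range {r_range}")
    if sites is None:
        sites = default_sites()
    rng = np.random.default_rng(seed)
    protons = []
    for i in range(n_protons):
        centre = sites.positions[rng.integers(len(sites))]
        r = rng.uniform(lo, hi)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        protons.append(
            Proton(label=f"P{i + 1}", residue_number=i + 1, group="amide",
                   methyl_id=None, position=centre + r * v)
        )
    pset = ProtonSet(protons)
    table = distance_table(pset, sites, methyl_average=False)
    meta = {"kind": "geometry", "seed": seed, "n_protons": n_protons,
            "r_range": list(r_range), "n_sites": len(sites)}
    return GeometryData(protons=pset, table=table, sites=sites, meta=meta)


# --- PRE field --------------------------------------------------------------

@dataclass
class PREData:
    observations: list[PREObservation]
    meta: dict


def gen_pre_field(
    coeffs: Sequence[float] = AMIDE_COEFFS,
    baseline: float = AMIDE_BASELINE,
    table: DistanceTable | None = None,
    noise_sd: float = 0.0,
    mark_broadened: bool = False,
    broadening_threshold: float = 6.0,
    seed: int = 0,
) -> PREData:
    """dR1 observations from the multi-site 1/r^6 model plus Gaussian noise.

    With ``mark_broadened`` every row closer than ``broadening_threshold``
    Å to its nearest site is flagged excluded, mimicking loss of severely
    broadened resonances.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if (coeffs < 0).any() or baseline < 0:
        raise ValueError("coefficients and baseline must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if table is None:
        table = gen_geometry(seed=seed).table
    rng = np.random.default_rng(seed)
    pred = predict_dr1(coeffs, table, baseline=baseline)
    noise = rng.normal(0.0, noise_sd, size=len(pred)) if noise_sd > 0 else np.zeros(len(pred))
    obs = []
    for label, value, eps in zip(table.labels, pred.to_numpy(), noise):
        broadened = mark_broadened and table.r_min_raw[label] < broadening_threshold
        obs.append(
            PREObservation(
                proton_label=label,
                dR1=float(value + eps),
                excluded=bool(broadened),
                reason="severe broadening" if broadened else "",
            )
        )
    meta = {"kind": "pre_field", "seed": seed, "coeffs_true": list(coeffs),
            "baseline_true": baseline, "noise_sd": noise_sd,
            "mark_broadened": mark_broadened, "scale": SCALE}
    return PREData(observations=obs, meta=meta)


# --- position trajectories --------------------------------------------------

@dataclass
class TrajectoryData:
    trajectory: PositionTrajectory
    meta: dict


def gen_position_traj(
    clusters: Sequence[tuple[Sequence[float], float, float]],
    n_frames: int = 1000,
    dt: float = 0.2e3,  # ps (0.2 ns between stored snapshots)
    seed: int = 0,
) -> TrajectoryData:
    """Frames drawn i.i.d. from a Gaussian mixture of position clusters.

    ``clusters`` is a list of ``(centre, sd, weight)``; weights must sum
    to 1.  Emulates the long-run occupancy density a bound ligand
    samples inside and around protein cavities.
    """
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    weights = np.array([w for _, _, w in clusters], dtype=float)
    if len(weights) == 0 or not math.isclose(weights.sum(), 1.0, rel_tol=0, abs_tol=1e-9) or (weights < 0).any():
        raise ValueError("cluster weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(clusters), size=n_frames, p=weights)
    frames = np.empty((n_frames, 3))
    for i, (centre, sd, _w) in enumerate(clusters):
        mask = which == i
        frames[mask] = np.asarray(centre, dtype=float) + rng.normal(0.0, sd, size=(mask.sum(), 3))
    meta = {"kind": "position_traj", "seed": seed, "n_frames": n_frames, "dt": dt,
            "clusters": [(list(map(float, c)), float(s), float(w)) for c, s, w in clusters],
            "assignments": which}
    return TrajectoryData(PositionTrajectory(dt=dt, frames=frames), meta)


def gen_scripted_traj(
    script: Sequence[tuple[int | str, int]],
    sites: SiteGeometry,
    dt: float = 0.2e3,
    jitter_sd: float = 0.2,
    outside_offset: float = 30.0,
    seed: int = 0,
) -> TrajectoryData:
    """A deterministic labelled path for event-detection tests.

    ``script`` is a list of ``(cavity_label_or_"outside", n_frames)``;
    frames are placed at the first site of the named cavity (plus small
    jitter well inside the assignment cutoff) or far outside the protein.
    """
    rng = np.random.default_rng(seed)
    frames = []
    labels = []
    far = np.array([outside_offset, outside_offset, outside_offset])
    for label, n in script:
        if n < 1:
            raise ValueError("script segments need >= 1 frame")
        if label == "outside":
            base = far
        else:
            in_cav = [s for s in sites if s.cavity == int(label)]
            if not in_cav:
                raise ValueError(f"no site in cavity {label}")
            base = in_cav[0].position
        for _ in range(n):
            frames.append(base + rng.normal(0.0, jitter_sd, size=3))
            labels.append(label if label == "outside" else int(label))
    meta = {"kind": "scripted_traj", "seed": seed, "script": list(script),
            "labels_true": labels, "dt": dt}
    return TrajectoryData(PositionTrajectory(dt=dt, frames=np.array(frames)), meta)


# --- orientation trajectories / ACF curves ----------------------------------

def gen_acf_curve(
    A: float = 0.5,
    tau_fast: float = 0.164,
    tau_slow: float = 1.41,
    dt: float = 0.01,
    max_lag: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """The analytic bi-exponential ACF sampled on a lag grid, plus noise.

    Returns ``(lags_ps, values, meta)``.  This is the ``acf_noise`` mode:
    it feeds the decay fitter directly without simulating vectors.
    """
    if not (0 < tau_fast <= tau_slow):
        raise ValueError("need 0 < tau_fast <= tau_slow")
    if not (0 <= A <= 1):
        raise ValueError("amplitude must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, max_lag + dt / 2, dt)
    c = A * np.exp(-t / tau_fast) + (1 - A) * np.exp(-t / tau_slow)
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=len(t))
    meta = {"kind": "acf_curve", "seed": seed, "A_true": A,
            "tau_fast_true": tau_fast, "tau_slow_true": tau_slow,
            "dt": dt, "noise_sd": noise_sd}
    return t, c, meta


def _rotate_about(u: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (u * np.cos(angle)
            + np.cross(axis, u) * np.sin(angle)
            + axis * np.dot(axis, u) * (1 - np.cos(angle)))


def gen_orientation_traj(
    tau_slow: float = 1.41,
    cone_semi_angle: float = 0.7,
    tau_wobble: float = 0.164,
    dt: float = 0.01,
    n_frames: int = 20000,
    seed: int = 0,
) -> tuple[OrientationTrajectory, dict]:
    """Unit-vector frames from wobbling-in-a-cone over slow isotropic diffusion.

    A cone axis undergoes isotropic rotational diffusion with
    ``D_slow = 1/(6 tau_slow)``; the bond vector wobbles rapidly inside a
    cone of the given semi-angle (radians) about that axis, relaxing with
    characteristic time ``tau_wobble``.  The rank-2 ACF of the result is
    approximately bi-exponential; a semi-angle of 0 collapses to pure
    single-exponential decay with ``tau = tau_slow``.
    """
    if dt > tau_wobble / 5 and cone_semi_angle > 0:
        raise ValueError(f"dt={dt} ps too coarse for tau_wobble={tau_wobble} ps")
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    rng = np.random.default_rng(seed)
    D_slow = 1.0 / (6.0 * tau_slow)
    sigma_slow = np.sqrt(2.0 * D_slow * dt)
    # wobble as an Ornstein–Uhlenbeck process on the two cone angles
    theta_relax = np.exp(-dt / tau_wobble)
    theta_eq_sd = cone_semi_angle / 2.0

    axis = np.array([0.0, 0.0, 1.0])
    tilt = np.zeros(2)  # small-angle offsets of u from the axis
    frames = np.empty((n_frames, 3))
    for i in range(n_frames):
        # slow isotropic diffusion of the axis: small random rotation
        step = rng.normal(0.0, sigma_slow, size=2)
        e1 = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(axis, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        axis = axis + step[0] * e1 + step[1] * e2
        axis /= np.linalg.norm(axis)
        if cone_semi_angle > 0:
            tilt = (theta_relax * tilt
                    + np.sqrt(1 - theta_relax**2) * rng.normal(0.0, theta_eq_sd, size=2))
            # reflect at the cone boundary
            amp = np.linalg.norm(tilt)
            if amp > cone_semi_angle:
                tilt *= (2 * cone_semi_angle - amp) / amp
            u = axis + tilt[0] * e1 + tilt[1] * e2
            u /= np.linalg.norm(u)
        else:
            u = axis
        frames[i] = u
    meta = {"kind": "orientation_traj", "seed": seed, "tau_slow": tau_slow,
            "tau_wobble": tau_wobble, "cone_semi_angle": cone_semi_angle,
            "dt": dt, "n_frames": n_frames}
    return OrientationTrajectory(dt=dt, frames=frames), meta


# --- structure fixtures -----------------------------------------------------

# idealized local geometry, Å offsets from the backbone N of each residue
_BACKBONE = {
    "N": (0.0, 0.0, 0.0),
    "H": (-0.6, 0.8, 0.0),
    "CA": (1.2, -0.8, 0.0),
    "C": (2.6, -0.2, 0.0),
    "O": (3.0, 0.9, 0.4),
}
_SIDECHAINS = {
    "ALA": {"CB": (1.4, -2.2, 0.6), "HB1": (0.9, -3.0, 1.1), "HB2": (2.1, -2.7, 0.0),
            "HB3": (2.0, -1.8, 1.4)},
    "VAL": {"CB": (1.4, -2.2, 0.6), "HB": (0.8, -2.0, 1.5),
            "CG1": (0.7, -3.2, -0.3), "HG11": (0.2, -4.0, 0.2), "HG12": (1.4, -3.7, -0.9),
            "HG13": (0.0, -2.8, -1.0),
            "CG2": (2.8, -2.9, 1.0), "HG21": (3.3, -3.3, 0.1), "HG22": (2.6, -3.7, 1.7),
            "HG23": (3.4, -2.2, 1.6)},
    "LEU": {"CB": (1.4, -2.2, 0.6), "HB2": (0.8, -2.1, 1.5), "HB3": (2.4, -2.2, 1.0),
            "CG": (1.1, -3.6, 0.0), "HG": (1.6, -3.7, -0.9),
            "CD1": (-0.4, -3.8, -0.3), "HD11": (-0.9, -3.9, 0.6), "HD12": (-0.6, -4.7, -0.9),
            "HD13": (-0.8, -3.0, -0.9),
            "CD2": (1.7, -4.7, 0.9), "HD21": (2.8, -4.6, 0.9), "HD22": (1.4, -5.7, 0.5),
            "HD23": (1.4, -4.6, 1.9)},
    "GLY": {},
}
_CHI_CYCLE = ("ALA", "VAL", "LEU")


@dataclass
class StructureFixture:
    pdb_text: str
    site_table_text: str | None
    meta: dict


def gen_structure_fixture(
    n_residues: int = 10,
    include_xe_sites: bool = False,
    n_sites: int = 5,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> StructureFixture:
    """A small poly-Ala/Val/Leu chain with explicit hydrogens as PDB text.

    Residues repeat the Ala–Val–Leu cycle along an extended axis
    (3.8 Å rise).  Optional xenon HETATM sites are appended near the
    chain, with their cavity labels in a sidecar site table (sites 1–3
    labelled cavity 4, the rest cavity 3, mirroring the five-site
    layout).  ``meta`` records exact atom counts for round-trip checks.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    lines = []
    serial = 0
    n_atoms = 0
    n_h = 0
    methyl_count = 0
    for ires in range(1, n_residues + 1):
        resname = _CHI_CYCLE[(ires - 1) % len(_CHI_CYCLE)]
        base = np.array([3.8 * (ires - 1), 0.0, 0.0])
        atoms = dict(_BACKBONE)
        atoms.update(_SIDECHAINS[resname])
        methyl_count += {"ALA": 1, "VAL": 2, "LEU": 2, "GLY": 0}[resname]
        for name, off in atoms.items():
            serial += 1
            n_atoms += 1
            pos = base + np.asarray(off) + rng.normal(0.0, jitter_sd, size=3)
            element = "H" if name.startswith("H") else name[0]
            if element == "H":
                n_h += 1
            name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            lines.append(
                f"ATOM  {serial:>5d} {name_field} {resname:<3s} A{ires:>4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
    site_table = None
    site_positions = []
    if include_xe_sites:
        site_rows = []
        for i in range(1, n_sites + 1):
            serial += 1
            n_atoms += 1
            pos = np.array([3.8 * n_residues + 4.0 * i, 2.0, 2.0]) + rng.normal(0.0, jitter_sd, size=3)
            site_positions.append(pos)
            lines.append(
                f"HETATM{serial:>5d}  XE  XE  A{900 + i:>4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          XE"
            )
            cavity = 4 if i <= 3 else 3
            site_rows.append(f"{i} {pos[0]:.3f} {pos[1]:.3f} {pos[2]:.3f} {cavity}")
        site_table = "# site_id x y z cavity\n" + "\n".join(site_rows) + "\n"
    pdb_text = "\n".join(lines) + "\nEND\n"
    meta = {"kind": "structure_fixture", "seed": seed, "n_residues": n_residues,
            "n_atoms": n_atoms, "n_hydrogens": n_h, "n_methyl_groups": methyl_count,
            "n_sites": n_sites if include_xe_sites else 0}
    return StructureFixture(pdb_text=pdb_text, site_table_text=site_table, meta=meta)
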