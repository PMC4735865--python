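"""Protein structures, proton selection and proton–site distance tables.

This module turns a hydrogen-bearing PDB structure plus a set of
paramagnet (xenon-proxy) site coordinates into the ``1/r^6`` distance
table that drives the multi-site PRE model.  All coordinates are in
ångström and PDB residue numbering is used verbatim.

Hydrogens are required: protonation is deliberately not performed here
(use an external tool such as the WHATIF server or ``reduce`` first).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Proton",
    "ProtonSet",
    "Site",
    "SiteGeometry",
    "DistanceTable",
    "StructureError",
    "StructureParseError",
    "NoProtonsError",
    "read_structure",
    "write_structure",
    "select_protons",
    "distance_table",
    "read_site_table",
    "sites_from_atoms",
]


class StructureError(Exception):
    """Base class for structure-handling errors."""


class StructureParseError(StructureError):
    """A PDB file could not be parsed; the message names the offending line."""


class NoProtonsError(StructureError):
    """The structure carries no hydrogen atoms."""


# ---------------------------------------------------------------------------
# Atom records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a PDB structure (ATOM or HETATM)."""

    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Å
    het: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {self.position}")
        if not self.element:
            raise ValueError(f"atom {self.atom_name} has empty element")
        object.__setattr__(self, "position", pos)


def _prevalidate_pdb_text(text: str, name: str) -> None:
    """Check that every ATOM/HETATM line has parseable coordinates."""
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except (ValueError, IndexError) as exc:
            raise StructureParseError(
                f"{name}, line {i}: cannot parse ATOM/HETATM record: {line!r}"
            ) from exc


def read_structure(path: str | Path) -> list[AtomRecord]:
    """Read a PDB file into a flat list of :class:`AtomRecord`.

    HETATM entries (e.g. xenon sites) are retained and flagged ``het=True``.
    """
    path = Path(path)
    text = path.read_text()
    _prevalidate_pdb_text(text, path.name)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise StructureParseError(f"{path.name}: {exc}") from exc
    records: list[AtomRecord] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    records.append(
                        AtomRecord(
                            residue_number=residue.seqid.num,
                            residue_name=residue.name.strip(),
                            atom_name=atom.name.strip(),
                            element=atom.element.name.upper(),
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            het=het,
                        )
                    )
        break  # first model only
    return records


def write_structure(atoms: Iterable[AtomRecord], path: str | Path) -> None:
    """Write atom records back out as minimal PDB text (3-decimal coordinates)."""
    buf = io.StringIO()
    for serial, a in enumerate(atoms, start=1):
        record = "HETATM" if a.het else "ATOM  "
        name = a.atom_name
        # PDB atom-name column convention: element right-justified in 13-14
        name_field = f" {name:<3s}" if len(name) < 4 and len(a.element) == 1 else f"{name:<4s}"
        buf.write(
            f"{record}{serial:>5d} {name_field} {a.residue_name:<3s} A"
            f"{a.residue_number:>4d}    "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
        )
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Proton selection
# ---------------------------------------------------------------------------

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Methyl groups observable as one resonance each: residue -> {tag: H atom names}
METHYL_GROUPS: dict[str, dict[str, tuple[str, str, str]]] = {
    "ALA": {"b": ("HB1", "HB2", "HB3")},
    "VAL": {"g1": ("HG11", "HG12", "HG13"), "g2": ("HG21", "HG22", "HG23")},
    "LEU": {"d1": ("HD11", "HD12", "HD13"), "d2": ("HD21", "HD22", "HD23")},
    "ILE": {"g2": ("HG21", "HG22", "HG23"), "d1": ("HD11", "HD12", "HD13")},
    "THR": {"g2": ("HG21", "HG22", "HG23")},
    "MET": {"e": ("HE1", "HE2", "HE3")},
}


@dataclass(frozen=True)
class Proton:
    label: str
    residue_number: int
    group: Literal["amide", "methyl"]
    methyl_id: str | None
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.group == "methyl" and not self.methyl_id:
            raise ValueError(f"methyl proton {self.label} lacks a methyl_id")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class ProtonSet:
    """An ordered set of amide and/or methyl protons with unique labels."""

    protons: list[Proton]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.protons]
        if len(labels) != len(set(labels)):
            dupes = {l for l in labels if labels.count(l) > 1}
            raise ValueError(f"duplicate proton labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.protons)

    def __iter__(self):
        return iter(self.protons)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.protons]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.protons]).reshape(len(self.protons), 3)

    def methyl_ids(self) -> list[str]:
        """Distinct methyl group ids in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.protons:
            if p.group == "methyl" and p.methyl_id not in seen:
                seen[p.methyl_id] = None
        return list(seen)


def _residue_label(resname: str, resnum: int) -> str:
    return f"{ONE_LETTER.get(resname, resname)}{resnum}"


def select_protons(atoms: Sequence[AtomRecord], mode: str = "both") -> ProtonSet:
    """Select backbone amide and/or methyl-group hydrogens.

    Amide mode picks backbone ``H`` atoms of standard residues; methyl mode
    picks the hydrogens of Ala β, Val γ1/γ2, Leu δ1/δ2, Ile γ2/δ1, Thr γ2
    and Met ε groups, tagging each with its per-resonance ``methyl_id``.
    """
    if mode not in ("amide", "methyl", "both"):
        raise ValueError(f"unknown proton-selection mode: {mode!r}")
    if not any(a.element == "H" for a in atoms):
        raise NoProtonsError(
            "no protons found in the structure; add hydrogens with an external "
            "protonation tool (e.g. the WHATIF server) before analysis"
        )
    # group atoms by residue, keeping order of first appearance
    residues: dict[tuple[int, str], list[AtomRecord]] = {}
    for a in atoms:
        if a.het:
            continue
        residues.setdefault((a.residue_number, a.residue_name), []).append(a)

    protons: list[Proton] = []
    for (resnum, resname), ratoms in residues.items():
        if mode in ("amide", "both"):
            for a in ratoms:
                if a.atom_name == "H" and a.element == "H":
                    protons.append(
                        Proton(
                            label=f"{_residue_label(resname, resnum)} H",
                            residue_number=resnum,
                            group="amide",
                            methyl_id=None,
                            position=a.position,
                        )
                    )
        if mode in ("methyl", "both") and resname in METHYL_GROUPS:
            by_name = {a.atom_name: a for a in ratoms if a.element == "H"}
            for tag, hnames in METHYL_GROUPS[resname].items():
                present = [by_name[n] for n in hnames if n in by_name]
                if len(present) != 3:
                    continue  # incomplete methyl: skip rather than guess
                mid = f"{_residue_label(resname, resnum)}{tag}"
                for a in present:
                    protons.append(
                        Proton(
                            label=f"{mid}:{a.atom_name}",
                            residue_number=resnum,
                            group="methyl",
                            methyl_id=mid,
                            position=a.position,
                        )
                    )
    return ProtonSet(protons)


# ---------------------------------------------------------------------------
# Paramagnet sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    site_id: int
    position: np.ndarray
    cavity: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class SiteGeometry:
    """Ordered paramagnet sites with cavity labels (site ids 1..n)."""

    sites: list[Site]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"site ids must be contiguous from 1, got {ids}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites]).reshape(len(self.sites), 3)

    @property
    def cavities(self) -> np.ndarray:
        return np.array([s.cavity for s in self.sites], dtype=int)

    def sites_in_cavity(self, cavity: int) -> list[int]:
        return [s.site_id for s in self.sites if s.cavity == cavity]


def read_site_table(path: str | Path) -> SiteGeometry:
    """Read sites from a plain table: ``site_id x y z cavity``.

    Whitespace- or comma-separated; ``#`` starts a comment.
    """
    sites = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 5:
            raise ValueError(f"site table line needs 5 columns, got: {raw!r}")
        sid, x, y, z, cav = parts
        sites.append(Site(int(sid), np.array([float(x), float(y), float(z)]), int(cav)))
    sites.sort(key=lambda s: s.site_id)
    return SiteGeometry(sites)


def sites_from_atoms(
    atoms: Sequence[AtomRecord],
    cavity_map: Mapping[int, int] | Sequence[int],
    element: str = "XE",
) -> SiteGeometry:
    """Build a :class:`SiteGeometry` from HETATM records of ``element``.

    Sites are numbered 1..n in file order; ``cavity_map`` gives the cavity
    label per site id (mapping) or per position (sequence).
    """
    het = [a for a in atoms if a.het and a.element == element.upper()]
    if not het:
        raise ValueError(f"no HETATM records with element {element!r} found")
    if not isinstance(cavity_map, Mapping):
        cavity_map = {i + 1: c for i, c in enumerate(cavity_map)}
    sites = []
    for i, a in enumerate(het, start=1):
        if i not in cavity_map:
            raise ValueError(f"no cavity label supplied for site {i}")
        sites.append(Site(i, a.position, int(cavity_map[i])))
    return SiteGeometry(sites)


# ---------------------------------------------------------------------------
# Distance tables
# ---------------------------------------------------------------------------

@dataclass
class DistanceTable:
    """Per-row effective ``1/r^6`` values (Å⁻⁶) and distances for each site.

    With methyl averaging, each methyl group contributes one row whose
    per-site ``1/r^6`` is the arithmetic mean over its three hydrogens;
    the stored distance is then the effective ``r = (1/r^6)^{-1/6}``.
    ``r_min_raw`` keeps the minimum raw proton–site distance per row, which
    the line-broadening screen uses.
    """

    labels: list[str]
    site_ids: list[int]
    inv6: pd.DataFrame  # rows × sites, Å⁻⁶
    r: pd.DataFrame  # rows × sites, Å (effective)
    r_min_raw: pd.Series  # per row, Å

    def __post_init__(self) -> None:
        if (self.inv6.values <= 0).any():
            raise ValueError("inverse-sixth-power values must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def matrix(self) -> np.ndarray:
        """The (n_rows, n_sites) array of 1/r^6 values, Å⁻⁶."""
        return self.inv6.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.r.add_prefix("r_"), self.inv6.add_prefix("inv6_")], axis=1)
        out.insert(0, "label", self.labels)
        out["r_min_raw"] = self.r_min_raw.to_numpy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceTable":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns:
            raise ValueError("distance table file needs a 'label' column")
        site_ids = [int(c[len("inv6_"):]) for c in df.columns if c.startswith("inv6_")]
        if not site_ids:
            raise ValueError("distance table file has no inv6_* columns")
        labels = df["label"].astype(str).tolist()
        inv6 = df[[f"inv6_{s}" for s in site_ids]].copy()
        inv6.columns = [str(s) for s in site_ids]
        inv6.index = labels
        r = df[[f"r_{s}" for s in site_ids]].copy()
        r.columns = [str(s) for s in site_ids]
        r.index = labels
        rmin_col = df["r_min_raw"] if "r_min_raw" in df.columns else r.min(axis=1)
        rmin = pd.Series(np.asarray(rmin_col, dtype=float), index=labels)
        return cls(labels, site_ids, inv6, r, rmin)


def distance_table(
    protons: ProtonSet,
    sites: SiteGeometry,
    methyl_average: bool = True,
) -> DistanceTable:
    """Compute the proton(-group)–site distance table.

    Raises if any proton coincides with a site (zero distance).
    """
    if len(protons) == 0 or len(sites) == 0:
        raise ValueError("distance_table needs non-empty protons and sites")
    ppos = protons.positions
    spos = sites.positions
    diff = ppos[:, None, :] - spos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))  # (n_protons, n_sites)
    if (dist == 0).any():
        ip, isite = np.argwhere(dist == 0)[0]
        raise ValueError(
            f"proton {protons.labels[ip]} coincides with site {sites.sites[isite].site_id}"
        )
    inv6 = dist**-6.0

    site_ids = [s.site_id for s in sites]
    cols = [str(s) for s in site_ids]

    if not methyl_average:
        labels = protons.labels
        inv6_df = pd.DataFrame(inv6, index=labels, columns=cols)
        r_df = pd.DataFrame(dist, index=labels, columns=cols)
        rmin = pd.Series(dist.min(axis=1), index=labels)
        return DistanceTable(labels, site_ids, inv6_df, r_df, rmin)

    rows: list[str] = []
    inv6_rows: list[np.ndarray] = []
    rmin_rows: list[float] = []
    seen_methyl: dict[str, list[int]] = {}
    order: list[tuple[str, str]] = []  # (kind, key) preserving first appearance
    for i, p in enumerate(protons):
        if p.group == "methyl":
            if p.methyl_id not in seen_methyl:
                order.append(("methyl", p.methyl_id))
            seen_methyl.setdefault(p.methyl_id, []).append(i)
        else:
            order.append(("single", str(i)))
    for kind, key in order:
        if kind == "single":
            i = int(key)
            rows.append(protons.protons[i].label)
            inv6_rows.append(inv6[i])
            rmin_rows.append(dist[i].min())
        else:
            idx = seen_methyl[key]
            rows.append(key)
            inv6_rows.append(inv6[idx].mean(axis=0))
            rmin_rows.append(dist[idx].min())
    inv6_arr = np.array(inv6_rows)
    inv6_df = pd.DataFrame(inv6_arr, index=rows, columns=cols)
    r_df = pd.DataFrame(inv6_arr ** (-1.0 / 6.0), index=rows, columns=cols)
    rmin = pd.Series(rmin_rows, index=rows)
    return DistanceTable(rows, site_ids, inv6_df, r_df, rmin)
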