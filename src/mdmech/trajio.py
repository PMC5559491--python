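"""Trajectory, topology and force-field file I/O.

Reads the LAMMPS dump text dialect, PSF topologies (X-PLOR and CHARMM,
plain and EXT widths) and CHARMM parameter (PRM) files into validated
in-memory structures, and writes analysis time series as CSV or JSON.

Units follow the LAMMPS "real" convention on input (see :mod:`mdmech.units`).
Positions are taken as unwrapped when ``xu yu zu`` columns exist; otherwise
wrapped coordinates are unwrapped with image flags when ``ix iy iz`` are
present; otherwise frames are flagged as wrapped and downstream kinematics
will refuse groups that span a periodic boundary.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParameterError

logger = logging.getLogger(__name__)

#: Component order used whenever a symmetric tensor is flattened.
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")
_TENSOR_INDEX = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Simulation cell: orthogonal or LAMMPS-style triclinic.

    ``lo``/``hi`` are the cell bounds (A), ``tilt`` the (xy, xz, yz)
    factors, and ``periodic_flags`` whether each direction is periodic.
    """

    lo: np.ndarray
    hi: np.ndarray
    tilt: np.ndarray = field(default_factory=lambda: np.zeros(3))
    periodic_flags: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        object.__setattr__(self, "tilt", np.asarray(self.tilt, dtype=float))
        if not np.all(hi > lo):
            raise IntegrityError(f"box hi must exceed lo componentwise: lo={lo}, hi={hi}")

    @property
    def lengths(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def is_triclinic(self) -> bool:
        return bool(np.any(self.tilt != 0.0))

    @property
    def h_matrix(self) -> np.ndarray:
        """Upper-triangular cell matrix (columns are the cell vectors)."""
        lx, ly, lz = self.lengths
        xy, xz, yz = self.tilt
        return np.array([[lx, xy, xz], [0.0, ly, yz], [0.0, 0.0, lz]])

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vector(s)."""
        d = np.asarray(d, dtype=float)
        single = d.ndim == 1
        d = np.atleast_2d(d)
        h = self.h_matrix
        s = np.linalg.solve(h, d.T).T
        for k in range(3):
            if self.periodic_flags[k]:
                s[:, k] -= np.round(s[:, k])
        out = (h @ s.T).T
        return out[0] if single else out

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass
class Frame:
    """One trajectory snapshot in LAMMPS "real" units."""

    timestep: int
    box: Box
    atom_ids: np.ndarray
    positions: np.ndarray
    type_ids: np.ndarray
    velocities: np.ndarray | None = None
    forces: np.ndarray | None = None
    unwrapped: bool = True

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        self.type_ids = np.asarray(self.type_ids, dtype=np.int64)
        n = len(self.atom_ids)
        if n == 0:
            raise IntegrityError(f"frame {self.timestep}: empty frame (zero atoms)")
        if len(np.unique(self.atom_ids)) != n:
            raise IntegrityError(f"frame {self.timestep}: duplicate atom id")
        for name in ("positions", "velocities", "forces"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n, 3):
                raise IntegrityError(
                    f"frame {self.timestep}: {name} shape {arr.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise IntegrityError(f"frame {self.timestep}: non-finite positions")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def index_of(self, atom_ids: Sequence[int]) -> np.ndarray:
        """Row indices of the given atom ids (ids are sorted ascending)."""
        idx = np.searchsorted(self.atom_ids, atom_ids)
        if np.any(idx >= self.n_atoms) or np.any(self.atom_ids[idx] != atom_ids):
            missing = set(np.asarray(atom_ids).tolist()) - set(self.atom_ids.tolist())
            raise IntegrityError(f"atom ids not present in frame: {sorted(missing)[:5]} ...")
        return idx


@dataclass
class Topology:
    """PSF content: per-atom static attributes and bonded connectivity.

    All connectivity tuples are 0-based indices into the per-atom arrays;
    atom *ids* (1-based in PSF) map to index ``id - 1``.
    """

    masses: np.ndarray
    charges: np.ndarray
    atom_type_names: list[str]
    residue_ids: np.ndarray
    residue_names: list[str]
    segment_names: list[str]
    atom_names: list[str]
    bonds: np.ndarray        # (nb, 2)
    angles: np.ndarray       # (na, 3)
    dihedrals: np.ndarray    # (nd, 4)
    impropers: np.ndarray    # (ni, 4)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        n = self.n_atoms
        if np.any(self.masses <= 0):
            raise IntegrityError("topology masses must be positive")
        for name, width in (("bonds", 2), ("angles", 3),
                            ("dihedrals", 4), ("impropers", 4)):
            arr = np.asarray(getattr(self, name), dtype=np.int64).reshape(-1, width)
            setattr(self, name, arr)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise FormatError(f"{name} reference atom index outside 1..{n}")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)


class FFParams:
    """CHARMM additive force-field parameters.

    Bonded terms are keyed by atom-type-name tuples (direction-insensitive);
    dihedral lookups fall back to wildcard ``X-B-C-X`` patterns and improper
    lookups to ``A-X-X-D``.  Nonbonded entries carry optional dedicated
    1-4 (eps14, rmin14/2) overrides.  ``eps`` is stored as a positive well
    depth (PRM files print it negative).
    """

    def __init__(self) -> None:
        self.bonds: dict[tuple[str, str], tuple[float, float]] = {}
        self.angles: dict[tuple[str, str, str], tuple[float, float, float, float]] = {}
        self.dihedrals: dict[tuple[str, str, str, str], dict[int, tuple[float, float]]] = {}
        self.impropers: dict[tuple[str, str, str, str], tuple[float, float]] = {}
        self.nonbonded: dict[str, tuple[float, float, float, float]] = {}
        self.cutoff: float = 12.0
        self.switch_start: float = 10.0
        self.dielectric: float = 1.0
        self.elec14_scale: float = 1.0

    # -- lookups ------------------------------------------------------------
    @staticmethod
    def _canon2(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @staticmethod
    def _canon3(a: str, b: str, c: str) -> tuple[str, str, str]:
        return (a, b, c) if a <= c else (c, b, a)

    @staticmethod
    def _canon4(a: str, b: str, c: str, d: str) -> tuple[str, str, str, str]:
        return min((a, b, c, d), (d, c, b, a))

    def bond_param(self, a: str, b: str) -> tuple[float, float]:
        try:
            return self.bonds[self._canon2(a, b)]
        except KeyError:
            raise ParameterError(f"no bond parameter for types ({a}, {b})") from None

    def angle_param(self, a: str, b: str, c: str) -> tuple[float, float, float, float]:
        try:
            return self.angles[self._canon3(a, b, c)]
        except KeyError:
            raise ParameterError(f"no angle parameter for types ({a}, {b}, {c})") from None

    def dihedral_terms(self, a: str, b: str, c: str, d: str) -> list[tuple[float, int, float]]:
        for key in (self._canon4(a, b, c, d), self._canon4("X", b, c, "X")):
            if key in self.dihedrals:
                return [(k, n, delta) for n, (k, delta) in sorted(self.dihedrals[key].items())]
        raise ParameterError(
            f"no dihedral parameter for types ({a}, {b}, {c}, {d}), wildcard included")

    def improper_param(self, a: str, b: str, c: str, d: str) -> tuple[float, float]:
        for key in (self._canon4(a, b, c, d), self._canon4(a, "X", "X", d)):
            if key in self.impropers:
                return self.impropers[key]
        raise ParameterError(
            f"no improper parameter for types ({a}, {b}, {c}, {d}), wildcard included")

    def nonbonded_param(self, t: str) -> tuple[float, float, float, float]:
        try:
            return self.nonbonded[t]
        except KeyError:
            raise ParameterError(f"no NONBONDED entry for atom type {t!r}") from None

    def validate_types(self, type_names: Iterable[str]) -> None:
        """Raise if any topology atom type lacks a NONBONDED entry."""
        missing = sorted({t for t in type_names if t not in self.nonbonded})
        if missing:
            raise ParameterError(f"atom types missing from NONBONDED: {missing}")


# ---------------------------------------------------------------------------
# LAMMPS dump reader
# ---------------------------------------------------------------------------

def _parse_box(bounds_header: str, lines: list[str]) -> Box:
    tokens = bounds_header.split()[3:]  # after "ITEM: BOX BOUNDS"
    triclinic = tokens[:3] == ["xy", "xz", "yz"]
    flag_tokens = tokens[3:6] if triclinic else tokens[:3]
    periodic = tuple(t.startswith("p") for t in (flag_tokens + ["p"] * 3)[:3])
    vals = [list(map(float, ln.split())) for ln in lines]
    if triclinic:
        (xlo_b, xhi_b, xy), (ylo_b, yhi_b, xz), (zlo_b, zhi_b, yz) = vals
        xlo = xlo_b - min(0.0, xy, xz, xy + xz)
        xhi = xhi_b - max(0.0, xy, xz, xy + xz)
        ylo = ylo_b - min(0.0, yz)
        yhi = yhi_b - max(0.0, yz)
        return Box(lo=[xlo, ylo, zlo_b], hi=[xhi, yhi, zhi_b],
                   tilt=[xy, xz, yz], periodic_flags=periodic)
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = [v[:2] for v in vals]
    return Box(lo=[xlo, ylo, zlo], hi=[xhi, yhi, zhi], periodic_flags=periodic)


def read_lammps_dump(path: str | Path,
                     fields_required: set[str] | None = None) -> list[Frame]:
    """Read a text LAMMPS dump file into a list of :class:`Frame`.

    Frames are sorted by timestep and atoms re-sorted by id within each
    frame.  Coordinates are unwrapped from ``xu yu zu`` columns, or from
    ``x y z`` plus ``ix iy iz`` image flags; wrapped-only frames are
    returned with ``unwrapped=False``.
    """
    path = Path(path)
    fields_required = set(fields_required or ())
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nline = len(lines)
    while i < nline:
        if not lines[i].startswith("ITEM: TIMESTEP"):
            if lines[i].strip() == "":
                i += 1
                continue
            raise FormatError(f"{path}: expected 'ITEM: TIMESTEP' at line {i + 1}")
        timestep = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise FormatError(f"{path}: expected 'ITEM: NUMBER OF ATOMS' at line {i + 3}")
        n_atoms = int(lines[i + 3])
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise FormatError(f"{path}: expected 'ITEM: BOX BOUNDS' at line {i + 5}")
        box = _parse_box(lines[i + 4], lines[i + 5:i + 8])
        atoms_header = lines[i + 8]
        if not atoms_header.startswith("ITEM: ATOMS"):
            raise FormatError(f"{path}: expected 'ITEM: ATOMS' at line {i + 9}")
        columns = atoms_header.split()[2:]
        col = {name: k for k, name in enumerate(columns)}
        for req in sorted(fields_required):
            if req not in col:
                raise FormatError(f"{path}: required column {req!r} missing "
                                  f"from ITEM: ATOMS header (has {columns})")
        if "id" not in col or "type" not in col:
            raise FormatError(f"{path}: dump must carry 'id' and 'type' columns")
        if n_atoms == 0:
            raise IntegrityError(f"{path}: frame {timestep} declares zero atoms")
        body = lines[i + 9:i + 9 + n_atoms]
        if len(body) < n_atoms:
            raise FormatError(f"{path}: truncated frame {timestep}")
        data = np.array([ln.split() for ln in body], dtype=float)
        if data.shape[1] != len(columns):
            raise FormatError(f"{path}: frame {timestep} row width != header width")

        ids = data[:, col["id"]].astype(np.int64)
        order = np.argsort(ids, kind="stable")
        data = data[order]
        ids = ids[order]

        unwrapped = True
        if {"xu", "yu", "zu"} <= col.keys():
            pos = data[:, [col["xu"], col["yu"], col["zu"]]]
        elif {"x", "y", "z"} <= col.keys():
            pos = data[:, [col["x"], col["y"], col["z"]]]
            if {"ix", "iy", "iz"} <= col.keys():
                images = data[:, [col["ix"], col["iy"], col["iz"]]]
                pos = pos + images @ box.h_matrix.T
            else:
                unwrapped = False
        else:
            raise FormatError(f"{path}: no coordinate columns (xu/yu/zu or x/y/z)")

        vel = data[:, [col["vx"], col["vy"], col["vz"]]] \
            if {"vx", "vy", "vz"} <= col.keys() else None
        frc = data[:, [col["fx"], col["fy"], col["fz"]]] \
            if {"fx", "fy", "fz"} <= col.keys() else None

        frames.append(Frame(timestep=timestep, box=box, atom_ids=ids,
                            positions=pos, type_ids=data[:, col["type"]].astype(np.int64),
                            velocities=vel, forces=frc, unwrapped=unwrapped))
        i += 9 + n_atoms
    frames.sort(key=lambda fr: fr.timestep)
    return frames


# ---------------------------------------------------------------------------
# PSF reader
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\s*(\d+)\s+!(\w+)")


def read_psf(path: str | Path) -> Topology:
    """Read an X-PLOR or CHARMM PSF (plain or EXT) into a :class:`Topology`."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or "PSF" not in lines[0]:
        raise FormatError(f"{path}: missing PSF header")

    sections: dict[str, tuple[int, int]] = {}
    counts: dict[str, int] = {}
    marks = [(i, m) for i, ln in enumerate(lines) if (m := _SECTION_RE.match(ln))]
    for k, (i, m) in enumerate(marks):
        end = marks[k + 1][0] if k + 1 < len(marks) else len(lines)
        name = m.group(2).upper()
        sections[name] = (i + 1, end)
        counts[name] = int(m.group(1))

    if "NATOM" not in sections:
        raise FormatError(f"{path}: no !NATOM section")
    n_atoms = counts["NATOM"]
    start, end = sections["NATOM"]
    atom_lines = [ln for ln in lines[start:end] if ln.strip()]
    if len(atom_lines) != n_atoms:
        raise FormatError(f"{path}: !NATOM declares {n_atoms} atoms, "
                          f"found {len(atom_lines)} records")

    seg, resid, resname, aname, atype = [], [], [], [], []
    charges, masses = [], []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 8:
            raise FormatError(f"{path}: short atom record: {ln!r}")
        seg.append(parts[1])
        resid.append(int(parts[2]))
        resname.append(parts[3])
        aname.append(parts[4])
        atype.append(parts[5])
        charges.append(float(parts[6]))
        masses.append(float(parts[7]))

    def read_tuples(name: str, width: int) -> np.ndarray:
        key = next((k for k in sections if k.startswith(name)), None)
        if key is None:
            return np.empty((0, width), dtype=np.int64)
        start, end = sections[key]
        flat: list[int] = []
        for ln in lines[start:end]:
            flat.extend(int(tok) for tok in ln.split())
        if len(flat) != counts[key] * width:
            raise FormatError(f"{path}: !{key} declares {counts[key]} entries "
                              f"but section holds {len(flat)} indices")
        arr = np.array(flat, dtype=np.int64).reshape(-1, width)
        if arr.size and (arr.min() < 1 or arr.max() > n_atoms):
            raise FormatError(f"{path}: !{key} references atom index outside 1..{n_atoms}")
        return arr - 1  # to 0-based

    return Topology(masses=masses, charges=charges, atom_type_names=atype,
                    residue_ids=resid, residue_names=resname,
                    segment_names=seg, atom_names=aname,
                    bonds=read_tuples("NBOND", 2), angles=read_tuples("NTHETA", 3),
                    dihedrals=read_tuples("NPHI", 4), impropers=read_tuples("NIMPHI", 4))


# ---------------------------------------------------------------------------
# CHARMM PRM reader
# ---------------------------------------------------------------------------

_PRM_SECTIONS = {"BONDS", "ANGLES", "DIHEDRALS", "IMPROPER", "IMPROPERS",
                 "NONBONDED", "CMAP", "NBFIX", "HBOND", "END", "ATOMS"}


def read_charmm_prm(path: str | Path) -> FFParams:
    """Read a CHARMM parameter file (BONDS/ANGLES/DIHEDRALS/IMPROPER/NONBONDED).

    Duplicate parameter lines: the last occurrence wins (a warning is
    logged); multi-term dihedrals (same type quadruple, different
    multiplicity) are accumulated.  Cutoff/switching distances are taken
    from ``cutnb/ctofnb/ctonnb`` tokens on the NONBONDED header when present.
    """
    path = Path(path)
    params = FFParams()
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("!")[0].rstrip()
            if not line.strip():
                continue
            head = line.split()[0].upper()
            if head in _PRM_SECTIONS:
                section = "IMPROPER" if head == "IMPROPERS" else head
                if section == "NONBONDED":
                    toks = line.split()
                    for key, attr in (("CTOFNB", "cutoff"), ("CTONNB", "switch_start")):
                        for k, t in enumerate(toks):
                            if t.upper() == key and k + 1 < len(toks):
                                setattr(params, attr, float(toks[k + 1]))
                if section == "END":
                    break
                continue
            parts = line.split()
            try:
                if section == "BONDS":
                    key = FFParams._canon2(parts[0], parts[1])
                    if key in params.bonds:
                        logger.warning("duplicate bond parameter %s: last wins", key)
                    params.bonds[key] = (float(parts[2]), float(parts[3]))
                elif section == "ANGLES":
                    key = FFParams._canon3(parts[0], parts[1], parts[2])
                    kub, s0 = (float(parts[5]), float(parts[6])) if len(parts) >= 7 \
                        else (0.0, 0.0)
                    if key in params.angles:
                        logger.warning("duplicate angle parameter %s: last wins", key)
                    params.angles[key] = (float(parts[3]), float(parts[4]), kub, s0)
                elif section == "DIHEDRALS":
                    key = FFParams._canon4(*parts[:4])
                    k, n, delta = float(parts[4]), int(parts[5]), float(parts[6])
                    terms = params.dihedrals.setdefault(key, {})
                    if n in terms:
                        logger.warning("duplicate dihedral term %s n=%d: last wins", key, n)
                    terms[n] = (k, delta)
                elif section == "IMPROPER":
                    key = FFParams._canon4(*parts[:4])
                    if key in params.impropers:
                        logger.warning("duplicate improper parameter %s: last wins", key)
                    params.impropers[key] = (float(parts[4]), float(parts[6]))
                elif section == "NONBONDED":
                    t = parts[0]
                    eps, rmin_half = abs(float(parts[2])), float(parts[3])
                    if len(parts) >= 7:
                        eps14, rmin14_half = abs(float(parts[5])), float(parts[6])
                    else:
                        eps14, rmin14_half = eps, rmin_half
                    if t in params.nonbonded:
                        logger.warning("duplicate NONBONDED entry %s: last wins", t)
                    params.nonbonded[t] = (eps, rmin_half, eps14, rmin14_half)
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed {section} line: {line!r}") from exc
    if params.cutoff <= params.switch_start:
        raise FormatError(f"{path}: cutoff ({params.cutoff}) must exceed "
                          f"switching start ({params.switch_start})")
    return params


# ---------------------------------------------------------------------------
# Time-series output
# ---------------------------------------------------------------------------

def _flatten_record(rec: Mapping[str, object]) -> dict[str, float]:
    out: dict[str, float] = {}
    for key, val in rec.items():
        arr = np.asarray(val)
        if arr.shape == ():
            out[key] = float(arr)
        elif arr.shape == (3,):
            for ax, v in zip("xyz", arr):
                out[f"{key}_{ax}"] = float(v)
        elif arr.shape == (3, 3):
            for comp, (i, j) in zip(TENSOR_COMPONENTS, _TENSOR_INDEX):
                out[f"{key}_{comp}"] = float(arr[i, j])
        else:
            raise FormatError(f"record field {key!r} has unsupported shape {arr.shape}")
    return out


def write_timeseries(records: Sequence[Mapping[str, object]],
                     path: str | Path, format: str = "csv",
                     columns: Sequence[str] | None = None) -> None:
    """Write per-frame records to CSV or JSON with a deterministic column order.

    3x3 tensors are flattened to six components in the order
    ``xx, yy, zz, xy, xz, yz``; 3-vectors to ``_x, _y, _z`` suffixes.
    All records must share one key schema.
    """
    path = Path(path)
    flat = [_flatten_record(r) for r in records]
    if flat:
        schema = list(flat[0].keys())
        for k, r in enumerate(flat):
            if list(r.keys()) != schema:
                raise FormatError(f"record {k} schema {list(r)} differs from {schema}")
    else:
        schema = list(columns or [])
    if format == "csv":
        pd.DataFrame(flat, columns=schema).to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump({"columns": schema,
                       "rows": [[r[c] for c in schema] for r in flat]}, fh)
    else:
        raise FormatError(f"unknown time-series format {format!r}")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read back a time series written by :func:`write_timeseries`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        try:
            return pd.DataFrame(payload["rows"], columns=payload["columns"])
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: malformed time-series JSON") from exc
    try:
        return pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: malformed time-series CSV") from exc
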