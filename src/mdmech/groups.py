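"""Named Lagrangian atom groups.

Groups are selected once on a designated reference frame and their
membership is frozen for the whole run: the analysis follows the same
material particles through deformation and rupture.  Selection rules
cover explicit id lists, residue-id ranges, and geometric rules evaluated
on reference-frame coordinates (cylinder about an axis, cylindrical
shells, and proximity to an existing group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, ValidationError
from .trajio import Frame, Topology


@dataclass(frozen=True)
class GroupSpec:
    """Declarative selection rule for one group.

    ``rule`` is one of ``explicit``, ``residue_range``, ``cylinder``,
    ``shell``, ``proximity``; the remaining fields parameterize the rule.
    Radial distances for cylinder/shell rules are measured in the membrane
    plane (perpendicular to ``axis``).  With ``by_molecule`` any residue
    touched by the rule is promoted to full membership.
    """

    name: str
    rule: str
    atom_ids: tuple[int, ...] = ()
    resid_range: tuple[int, int] | None = None
    segment: str | None = None
    center: tuple[float, float, float] | None = None
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float | None = None
    inner_radius: float | None = None
    outer_radius: float | None = None
    target: str | None = None          # name of the proximity target group
    distance: float | None = None      # proximity cutoff (A)
    heavy_only: bool = False           # proximity measured to heavy atoms only
    by_molecule: bool = False

    def __post_init__(self) -> None:
        if self.rule not in ("explicit", "residue_range", "cylinder",
                             "shell", "proximity"):
            raise ValidationError(f"unknown group rule {self.rule!r}")
        if self.rule == "cylinder" and not (self.radius and self.radius > 0):
            raise ValidationError(f"group {self.name!r}: cylinder radius must be > 0")
        if self.rule == "shell":
            if not (self.inner_radius is not None and self.outer_radius is not None
                    and 0 <= self.inner_radius < self.outer_radius):
                raise ValidationError(
                    f"group {self.name!r}: shell needs 0 <= inner < outer radius")
        if self.rule == "proximity" and not (self.distance and self.distance > 0):
            raise ValidationError(f"group {self.name!r}: proximity distance must be > 0")


@dataclass(frozen=True)
class AtomGroup:
    """An ordered, frozen set of atom ids with its selection provenance."""

    name: str
    atom_ids: np.ndarray
    spec: GroupSpec
    reference_frame: int

    def __post_init__(self) -> None:
        ids = np.unique(np.asarray(self.atom_ids, dtype=np.int64))
        object.__setattr__(self, "atom_ids", ids)

    def __len__(self) -> int:
        return len(self.atom_ids)

    def __contains__(self, atom_id: int) -> bool:
        i = np.searchsorted(self.atom_ids, atom_id)
        return i < len(self.atom_ids) and self.atom_ids[i] == atom_id


def _inplane_radii(positions: np.ndarray, center: np.ndarray,
                   axis: np.ndarray) -> np.ndarray:
    """Distance from the axis line, measured perpendicular to ``axis``."""
    d = positions - center
    d_perp = d - np.outer(d @ axis, axis)
    return np.linalg.norm(d_perp, axis=1)


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("axis vector must be nonzero")
    return v / n


def select_group(frame: Frame, topo: Topology, spec: GroupSpec,
                 known_groups: dict[str, AtomGroup] | None = None) -> AtomGroup:
    """Evaluate a :class:`GroupSpec` on the reference frame.

    Membership is decided on reference-frame coordinates and frozen
    thereafter (Lagrangian group).  Raises :class:`SelectionError` with
    diagnostic counts if the rule selects nothing.
    """
    known_groups = known_groups or {}
    n = frame.n_atoms
    if topo.n_atoms != n:
        raise ValidationError(f"topology has {topo.n_atoms} atoms, frame has {n}")
    # frame rows are sorted by id; topology arrays are in id order too
    mask = np.zeros(n, dtype=bool)

    if spec.rule == "explicit":
        idx = frame.index_of(np.asarray(spec.atom_ids, dtype=np.int64))
        mask[idx] = True
    elif spec.rule == "residue_range":
        lo, hi = spec.resid_range
        mask = (topo.residue_ids >= lo) & (topo.residue_ids <= hi)
        if spec.segment is not None:
            mask &= np.array([s == spec.segment for s in topo.segment_names])
    elif spec.rule in ("cylinder", "shell"):
        axis = _unit(spec.axis)
        center = np.asarray(spec.center if spec.center is not None
                            else frame.positions.mean(axis=0), dtype=float)
        r = _inplane_radii(frame.positions, center, axis)
        if spec.rule == "cylinder":
            mask = r <= spec.radius
        else:
            mask = (r > spec.inner_radius) & (r <= spec.outer_radius)
    elif spec.rule == "proximity":
        if spec.target not in known_groups:
            raise ValidationError(
                f"group {spec.name!r}: proximity target {spec.target!r} not defined")
        target = known_groups[spec.target]
        tgt_idx = frame.index_of(target.atom_ids)
        if spec.heavy_only:
            tgt_idx = tgt_idx[topo.masses[tgt_idx] > 3.5]
        tree = cKDTree(frame.positions[tgt_idx])
        dist, _ = tree.query(frame.positions, k=1)
        mask = dist <= spec.distance
        mask[tgt_idx] = False  # the target itself is not its own shell

    if spec.by_molecule and mask.any():
        # promote any partially selected residue to full membership
        key = np.stack([topo.residue_ids,
                        np.unique(topo.segment_names, return_inverse=True)[1]], axis=1)
        selected = {tuple(k) for k in key[mask]}
        mask = np.array([tuple(k) in selected for k in key])

    if not mask.any():
        raise SelectionError(
            f"group {spec.name!r}: rule {spec.rule!r} selected 0 of {n} atoms "
            f"on reference frame {frame.timestep}")
    return AtomGroup(name=spec.name, atom_ids=frame.atom_ids[mask], spec=spec,
                     reference_frame=frame.timestep)


def group_disjointness(a: AtomGroup, b: AtomGroup) -> tuple[bool, np.ndarray]:
    """Whether two groups share no atoms, plus the overlapping ids."""
    overlap = np.intersect1d(a.atom_ids, b.atom_ids)
    return len(overlap) == 0, overlap


def write_group(group: AtomGroup, path: str | Path) -> None:
    """Persist a group as a plain id list with header metadata."""
    with open(path, "w") as fh:
        fh.write(f"# group {group.name}\n")
        fh.write(f"# rule {group.spec.rule}\n")
        fh.write(f"# reference_frame {group.reference_frame}\n")
        fh.write(f"# n_atoms {len(group)}\n")
        for i in group.atom_ids:
            fh.write(f"{i}\n")


def read_group(path: str | Path) -> AtomGroup:
    """Read back a persisted group file."""
    name, ref = Path(path).stem, 0
    ids = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["group"]:
                    name = parts[1]
                elif parts[:1] == ["reference_frame"]:
                    ref = int(parts[1])
                continue
            if line.strip():
                ids.append(int(line))
    spec = GroupSpec(name=name, rule="explicit", atom_ids=tuple(ids))
    return AtomGroup(name=name, atom_ids=np.array(ids, dtype=np.int64),
                     spec=spec, reference_frame=ref)
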