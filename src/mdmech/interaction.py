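"""Cross-group interaction force and surface-averaged interaction stress.

The interaction stress between two disjoint groups is the resultant force
one exerts on the other, normalized by the area of their interface.  For a
membrane inclusion the interface is taken as the *lateral* (in-plane
facing) surface of the inner group — the rupture mode of interest is
in-plane separation of lipids from the inclusion — so top/bottom caps are
excluded.  The interface is re-evaluated per frame by default (the
inclusion's footprint evolves under stretch); a frozen reference area is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .ffeval import PairForceSet, cross_group_force
from .groups import AtomGroup, group_disjointness
from .trajio import Frame
from .units import KCAL_PER_MOL_A_TO_PN

#: 1 pN/nm^2 = 1 MPa; areas here are in A^2 (100 A^2 = 1 nm^2).
_PN_PER_A2_TO_MPA = 100.0


@dataclass(frozen=True)
class InteractionState:
    """Continuum interaction measures between two groups at one frame."""

    force_ab: np.ndarray       # resultant force of b on a, kcal/mol/A
    force_ab_pn: np.ndarray    # same, pN
    interface_area: float      # A^2
    traction_mpa: np.ndarray   # resultant force / area, MPa
    sigma_int_axial: float     # tension-resolved axial traction, MPa
    groups: tuple[str, str]
    frame: int


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(axis @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - (trial @ axis) * axis
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def interface_area(frame: Frame, inner: AtomGroup, outer: AtomGroup,
                   method: str = "cylinder",
                   membrane_normal=(0.0, 0.0, 1.0)) -> float:
    """Lateral interface area (A^2) between an inner group and its surroundings.

    ``cylinder``: perimeter of the inner group's projected 2-D convex hull
    times the inner group's extent along the membrane normal.
    ``hull_band``: summed area of the inner group's 3-D hull facets whose
    outward normal lies mostly in-plane (within 45 degrees of the membrane
    plane).
    """
    disjoint, overlap = group_disjointness(inner, outer)
    if not disjoint:
        raise ValidationError(f"groups {inner.name!r}/{outer.name!r} overlap "
                              f"({len(overlap)} atoms)")
    normal = np.asarray(membrane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    pos = frame.positions[frame.index_of(inner.atom_ids)]
    thickness = float(np.ptp(pos @ normal))
    if method == "cylinder":
        u, v = _plane_basis(normal)
        pts2d = np.stack([pos @ u, pos @ v], axis=1)
        try:
            hull = ConvexHull(pts2d)
        except QhullError as exc:
            raise ValidationError(f"degenerate in-plane projection: {exc}") from exc
        verts = pts2d[hull.vertices]
        perimeter = float(np.linalg.norm(np.roll(verts, -1, axis=0) - verts,
                                         axis=1).sum())
        if thickness <= 0 or perimeter <= 0:
            raise ValidationError("degenerate interface (zero perimeter or thickness)")
        return perimeter * thickness
    if method == "hull_band":
        try:
            hull = ConvexHull(pos)
        except QhullError as exc:
            raise ValidationError(f"degenerate inner-group hull: {exc}") from exc
        tri = pos[hull.simplices]
        n_raw = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        areas = 0.5 * np.linalg.norm(n_raw, axis=1)
        with np.errstate(invalid="ignore"):
            cos_to_normal = np.abs(n_raw @ normal) / (2.0 * areas)
        lateral = areas[(areas > 0) & (cos_to_normal < np.cos(np.deg2rad(45.0)))]
        if lateral.size == 0:
            raise ValidationError("no lateral hull facets found for interface area")
        return float(lateral.sum())
    raise ValidationError(f"unknown interface-area method {method!r}")


def interaction_stress(force_ab: np.ndarray, area: float,
                       axis=(1.0, 0.0, 0.0)) -> tuple[float, np.ndarray]:
    """Surface-averaged interaction stress from a resultant force.

    ``force_ab`` in kcal/mol/A, ``area`` in A^2; returns the axial
    component (MPa, along ``axis``) and the full traction vector (MPa).
    Unit identity: 1 pN/nm^2 = 1 MPa.
    """
    if area <= 0:
        raise ValidationError("interface area must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    force_pn = np.asarray(force_ab, dtype=float) * KCAL_PER_MOL_A_TO_PN
    traction_mpa = force_pn / area * _PN_PER_A2_TO_MPA
    return float(axis @ traction_mpa), traction_mpa


def axial_interface_tension(frame: Frame, pairs: PairForceSet,
                            a: AtomGroup, b: AtomGroup, area: float,
                            axis=(1.0, 0.0, 0.0)) -> float:
    """Axial surface-averaged interaction stress, tension-resolved (MPa).

    For a closed interface under symmetric uniaxial tension the *resultant*
    of the cross-group forces cancels between the two axial poles, yet each
    half-interface carries a real tensile traction.  This measure resolves
    the cross-pair forces on the axial-facing half-interfaces: pair forces
    acting on ``a``-atoms on the +axis side of ``a``'s centroid count with
    their sign, those on the -axis side with opposite sign, and the sum is
    normalized by the full interface area.  For a one-sided interface it
    reduces to the axial component of resultant/area.  Positive when the
    surroundings pull the inclusion apart along the axis.
    """
    if area <= 0:
        raise ValidationError("interface area must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    idx_a = frame.index_of(a.atom_ids)
    centroid = frame.positions[idx_a].mean(axis=0)

    ids_i = pairs.atom_ids[pairs.i]
    ids_j = pairs.atom_ids[pairs.j]
    in_a_i = np.isin(ids_i, a.atom_ids)
    in_a_j = np.isin(ids_j, a.atom_ids)
    in_b_i = np.isin(ids_i, b.atom_ids)
    in_b_j = np.isin(ids_j, b.atom_ids)
    fwd = in_a_i & in_b_j          # stored f_ij acts on the a-member i
    rev = in_b_i & in_a_j          # a-member is j: force on a is -f_ij
    total = 0.0
    for sel, rows, sign in ((fwd, pairs.i, 1.0), (rev, pairs.j, -1.0)):
        if not np.any(sel):
            continue
        x_a = frame.positions[rows[sel]]
        side = np.sign((x_a - centroid) @ axis)
        t_ax = sign * (pairs.f_ij[sel] @ axis)
        total += float(np.sum(side * t_ax))
    return total * KCAL_PER_MOL_A_TO_PN / area * _PN_PER_A2_TO_MPA


def interaction_state(frame: Frame, pairs: PairForceSet,
                      a: AtomGroup, b: AtomGroup,
                      axis=(1.0, 0.0, 0.0),
                      area_method: str = "cylinder",
                      membrane_normal=(0.0, 0.0, 1.0),
                      frozen_area: float | None = None) -> InteractionState:
    """Full interaction record: force of ``b`` on ``a`` over their interface.

    ``a`` is the inner group (the inclusion); pass ``frozen_area`` to
    normalize by a reference interface area instead of the current one.
    """
    force = cross_group_force(pairs, a, b)
    area = frozen_area if frozen_area is not None else \
        interface_area(frame, a, b, method=area_method,
                       membrane_normal=membrane_normal)
    _, traction = interaction_stress(force, area, axis=axis)
    axial = axial_interface_tension(frame, pairs, a, b, area, axis=axis)
    return InteractionState(force_ab=force,
                            force_ab_pn=force * KCAL_PER_MOL_A_TO_PN,
                            interface_area=area, traction_mpa=traction,
                            sigma_int_axial=axial,
                            groups=(a.name, b.name), frame=frame.timestep)
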