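"""Deformation kinematics of atom groups.

The best affine map ``x = F X + c`` between the reference and current
configuration of a group is fitted by (optionally weighted) least squares;
the Green-Lagrange strain ``E = (F^T F - I) / 2`` then measures the
group's deformation free of rigid motions.  Per-frame fits are independent
(total-Lagrangian, always against the same reference frame), so no
incremental drift accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import KinematicsError, ValidationError
from .groups import AtomGroup
from .trajio import Frame
from .units import PER_FS_TO_PER_S

_AXIS_NAMES = "xyz"


@dataclass(frozen=True)
class DeformationState:
    """Fitted affine deformation of one group at one frame."""

    F: np.ndarray            # 3x3 deformation gradient
    c: np.ndarray            # translation, A
    E: np.ndarray            # 3x3 Green-Lagrange strain
    residual_rms: float      # A
    n_atoms: int
    frame: int

    @property
    def det_F(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def volumetric_ok(self) -> bool:
        """False when the fit inverted (det F <= 0)."""
        return self.det_F > 0.0


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain ``E = (F^T F - I)/2``; symmetric by construction."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValidationError("deformation gradient contains non-finite entries")
    return 0.5 * (F.T @ F - np.eye(3))


def fit_deformation_gradient(ref_positions: np.ndarray,
                             cur_positions: np.ndarray,
                             weights: np.ndarray | None = None,
                             frame: int = 0) -> DeformationState:
    """Least-squares fit of ``(F, c)`` minimizing sum w_i |x_i - F X_i - c|^2.

    Closed-form normal-equation solution: with weighted-centroid-removed
    coordinates X', x', ``F = (sum w x' X'^T)(sum w X' X'^T)^{-1}``.
    Requires at least 4 atoms whose reference covariance has full rank
    (non-coplanar reference geometry).
    """
    X = np.asarray(ref_positions, dtype=float)
    x = np.asarray(cur_positions, dtype=float)
    if X.shape != x.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValidationError("reference/current position arrays must both be (n, 3)")
    n = len(X)
    if n < 4:
        raise KinematicsError(f"deformation fit needs >= 4 atoms, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValidationError("weights must be non-negative with positive sum")
    w = w / w.sum()

    Xm = w @ X
    xm = w @ x
    Xc = X - Xm
    xc = x - xm
    cov = (w[:, None] * Xc).T @ Xc          # reference covariance
    cross = (w[:, None] * xc).T @ Xc
    eigval, eigvec = np.linalg.eigh(cov)
    rel = eigval / eigval.max()
    if np.any(rel < 1e-12):
        k = int(np.argmin(rel))
        direction = eigvec[:, k]
        axis = _AXIS_NAMES[int(np.argmax(np.abs(direction)))]
        raise KinematicsError(
            "reference configuration is rank-deficient (coplanar/collinear) "
            f"along direction ~{axis} ({direction.round(3)})")
    F = cross @ np.linalg.inv(cov)
    c = xm - F @ Xm
    res = x - X @ F.T - c
    rms = float(np.sqrt(np.sum(w[:, None] * res ** 2)))
    return DeformationState(F=F, c=c, E=green_lagrange(F),
                            residual_rms=rms, n_atoms=n, frame=frame)


def fit_group_deformation(ref_frame: Frame, cur_frame: Frame, group: AtomGroup,
                          weights: np.ndarray | None = None) -> DeformationState:
    """Fit the deformation of ``group`` between two frames."""
    for fr in (ref_frame, cur_frame):
        if not fr.unwrapped:
            raise KinematicsError(
                f"frame {fr.timestep} has wrapped coordinates without image flags; "
                "deformation fitting requires unwrapped positions")
    ref_idx = ref_frame.index_of(group.atom_ids)
    cur_idx = cur_frame.index_of(group.atom_ids)
    return fit_deformation_gradient(ref_frame.positions[ref_idx],
                                    cur_frame.positions[cur_idx],
                                    weights=weights, frame=cur_frame.timestep)


def _projected_hull_area(positions: np.ndarray, plane_normal: np.ndarray) -> float:
    normal = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(normal)
    if not np.isclose(nn, 1.0, atol=1e-8):
        raise ValidationError("plane normal must be unit length")
    # orthonormal in-plane basis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(normal @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - (trial @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    pts2d = np.stack([positions @ u, positions @ v], axis=1)
    if len(np.unique(pts2d.round(9), axis=0)) < 3:
        raise KinematicsError("degenerate projected geometry (<3 distinct points)")
    try:
        hull = ConvexHull(pts2d)
    except QhullError as exc:
        raise KinematicsError(f"degenerate projected hull: {exc}") from exc
    return float(hull.volume)  # 2-D hull "volume" is the enclosed area


def areal_strain(ref_frame: Frame, cur_frame: Frame, group: AtomGroup,
                 plane_normal=(0.0, 0.0, 1.0)) -> float:
    """In-plane areal strain ``(A - A0)/A0`` of a membrane group.

    The area is the 2-D convex hull of the group's atoms projected on the
    membrane plane.
    """
    if len(group) == 0:
        raise ValidationError("areal strain of an empty group")
    normal = np.asarray(plane_normal, dtype=float)
    ref_idx = ref_frame.index_of(group.atom_ids)
    cur_idx = cur_frame.index_of(group.atom_ids)
    a0 = _projected_hull_area(ref_frame.positions[ref_idx], normal)
    a = _projected_hull_area(cur_frame.positions[cur_idx], normal)
    return (a - a0) / a0


def box_lateral_area(frame: Frame, plane_normal=(0.0, 0.0, 1.0)) -> float:
    """Alternative whole-patch area: the box face perpendicular to the normal."""
    normal = np.abs(np.asarray(plane_normal, dtype=float))
    k = int(np.argmax(normal))
    lengths = frame.box.lengths
    return float(np.prod(np.delete(lengths, k)))


@dataclass
class StrainSeries:
    """Axial / transverse strain bookkeeping across a run."""

    frames: np.ndarray               # timesteps, strictly increasing
    axial: np.ndarray                # axial Green-Lagrange component
    inplane_transverse: np.ndarray
    outofplane: np.ndarray
    loading_axis: np.ndarray
    rate_label: float = float("nan")  # s^-1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError("strain series frames must be strictly increasing")


def engineering_axial(separations: np.ndarray, l0: float,
                      times_fs: np.ndarray | None = None,
                      warn=None) -> tuple[np.ndarray, float]:
    """Engineering strain ``(L - L0)/L0`` and its rate (s^-1) by linear fit.

    ``separations`` are piston separations L(t) in A; ``times_fs`` the frame
    times in fs (defaults to a unit-spaced grid, giving the rate per frame).
    A non-monotone L under nominally constant-speed loading triggers the
    ``warn`` callback (or a log record) but is not an error.
    """
    L = np.asarray(separations, dtype=float)
    if l0 <= 0:
        raise ValidationError("reference separation L0 must be positive")
    strain = (L - l0) / l0
    if len(L) > 2 and np.any(np.diff(L) < 0) and np.any(np.diff(L) > 0):
        message = "piston separation is non-monotone under constant-speed protocol"
        if warn is not None:
            warn(message)
        else:
            import logging
            logging.getLogger(__name__).warning(message)
    t = np.arange(len(L), dtype=float) if times_fs is None \
        else np.asarray(times_fs, dtype=float)
    if len(L) < 2 or np.ptp(t) == 0 or np.ptp(strain) == 0:
        return strain, 0.0
    slope = np.polyfit(t, strain, 1)[0]          # per fs
    rate = slope * PER_FS_TO_PER_S if times_fs is not None else slope
    return strain, float(rate)
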