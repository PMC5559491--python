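"""End-to-end extraction: trajectory -> strain / stress / interaction series.

This is the library form of the workflow the command line drives: fit the
deformation of the surrounding-lipid group against the reference frame,
build the pairwise force decomposition per frame, and record the internal
stress of the surrounding group and the interaction stress exerted on the
inclusion, all keyed by frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MDMechError
from .ffeval import pairwise_decompose
from .groups import AtomGroup
from .interaction import interaction_state
from .kinematics import areal_strain, fit_group_deformation
from .rupture import StressStrainCurve
from .stress import group_volume, internal_stress, surface_average
from .trajio import FFParams, Frame, Topology

_AXES = {"x": np.array([1.0, 0.0, 0.0]),
         "y": np.array([0.0, 1.0, 0.0]),
         "z": np.array([0.0, 0.0, 1.0])}


def axis_vector(name_or_vec) -> np.ndarray:
    """'x'/'y'/'z' or an explicit 3-vector -> unit 3-vector."""
    if isinstance(name_or_vec, str):
        try:
            return _AXES[name_or_vec.lower()].copy()
        except KeyError:
            raise MDMechError(f"unknown axis name {name_or_vec!r}") from None
    v = np.asarray(name_or_vec, dtype=float)
    return v / np.linalg.norm(v)


def engineering_from_green_lagrange(e_axial: float) -> float:
    """Axial engineering strain from the axial Green-Lagrange component.

    The axial stretch is ``lambda = sqrt(1 + 2 E_aa)``; engineering strain
    is ``lambda - 1``.
    """
    val = 1.0 + 2.0 * e_axial
    if val <= 0:
        raise MDMechError(f"unphysical Green-Lagrange axial component {e_axial}")
    return float(np.sqrt(val) - 1.0)


@dataclass
class ExtractionResult:
    """Per-frame records of one extraction run, ready for write_timeseries."""

    strain_records: list[dict] = field(default_factory=list)
    internal_records: list[dict] = field(default_factory=list)
    interaction_records: list[dict] = field(default_factory=list)
    system: str = ""
    rate_label: float = float("nan")

    def stress_strain_curve(self) -> StressStrainCurve:
        """Rupture-analysis curve: lipid axial strain vs axial interaction stress."""
        strain = np.array([r["axial_strain"] for r in self.strain_records])
        stress = np.array([r["sigma_int_axial_mpa"]
                           for r in self.interaction_records])
        areal = np.array([r["areal_strain"] for r in self.strain_records])
        return StressStrainCurve(strain=strain, stress_mpa=stress,
                                 areal_strain=areal, system=self.system,
                                 rate_label=self.rate_label)


def extract_series(frames: list[Frame], topo: Topology, params: FFParams,
                   inner: AtomGroup, outer: AtomGroup,
                   reference_index: int = 0,
                   loading_axis="x", membrane_normal="z",
                   include_kinetic: bool = False,
                   volume_method: str = "hull",
                   slab_thickness: float | None = None,
                   area_method: str = "cylinder",
                   system: str = "", rate_label: float = float("nan"),
                   progress_every: int = 100) -> ExtractionResult:
    """Run the full extraction over a trajectory.

    ``outer`` is the surrounding-lipid group whose deformation and internal
    stress are tracked; ``inner`` the inclusion on which the interaction
    stress acts.  The strain axis of record is the axial engineering strain
    of the outer group derived from its fitted Green-Lagrange strain; the
    piston (box-schedule) strain is recorded alongside.
    """
    import logging
    log = logging.getLogger(__name__)

    axis = axis_vector(loading_axis)
    normal = axis_vector(membrane_normal)
    ref = frames[reference_index]
    # in-plane transverse direction completes the (axis, normal) frame
    trans = np.cross(normal, axis)
    trans /= np.linalg.norm(trans)

    result = ExtractionResult(system=system, rate_label=rate_label)
    for k, frame in enumerate(frames):
        try:
            deform = fit_group_deformation(ref, frame, outer)
            e_axial = float(axis @ deform.E @ axis)
            e_trans = float(trans @ deform.E @ trans)
            e_normal = float(normal @ deform.E @ normal)
            a_strain = areal_strain(ref, frame, outer, plane_normal=normal)
            piston = float(frame.box.lengths @ np.abs(axis)
                           / (ref.box.lengths @ np.abs(axis)) - 1.0)
            result.strain_records.append({
                "frame": frame.timestep,
                "axial_strain": engineering_from_green_lagrange(e_axial),
                "E_axial": e_axial,
                "E_inplane_transverse": e_trans,
                "E_outofplane": e_normal,
                "inplane_transverse_strain":
                    engineering_from_green_lagrange(e_trans),
                "outofplane_strain": engineering_from_green_lagrange(e_normal),
                "areal_strain": a_strain,
                "piston_strain": piston,
                "fit_residual_rms": deform.residual_rms})

            pairs = pairwise_decompose(frame, topo, params)
            vol = group_volume(frame, outer, method=volume_method,
                               slab_thickness=slab_thickness,
                               plane_normal=normal)
            st = internal_stress(frame, outer, pairs, vol, topo=topo,
                                 include_kinetic=include_kinetic)
            _, axial_internal = surface_average(st.sigma, axis)
            result.internal_records.append({
                "frame": frame.timestep,
                "sigma_axial_mpa": axial_internal,
                "sigma": st.sigma,
                "volume_a3": vol})

            inter = interaction_state(frame, pairs, inner, outer, axis=axis,
                                      area_method=area_method,
                                      membrane_normal=normal)
            result.interaction_records.append({
                "frame": frame.timestep,
                "sigma_int_axial_mpa": inter.sigma_int_axial,
                "force_pn": inter.force_ab_pn,
                "interface_area_a2": inter.interface_area})
        except MDMechError as exc:
            raise type(exc)(
                f"frame {frame.timestep} (groups {inner.name}/{outer.name}): {exc}"
            ) from exc
        if progress_every and (k + 1) % progress_every == 0:
            log.info("processed %d/%d frames", k + 1, len(frames))
    return result
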