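"""Synthetic input generators.

Everything the analysis surface consumes can be generated here with exact
ground truth: affinely deformed point clouds (kinematics validation), tiny
bonded/nonbonded systems with closed-form virials (force-field and stress
validation), and a mock two-leaflet membrane patch with an embedded
inclusion under piston stretch with programmed cohesive failure (end-to-end
pipeline validation).  Generators also write standard LAMMPS dump, PSF and
PRM files so fixtures exercise the real I/O path.

The mock membrane is synthesized quasi-statically — prescribed displacement
fields plus irreversible detachment of cohesive bonds — not integrated
dynamics: the artifact is a post-processor and ground truth must be exact.
The cohesive rule is the minimal mechanism producing a peaked
interaction-stress curve with a controllable rupture strain:

* surrounding lipids follow the uniaxial stretch ``diag(1+e, 1-nu e, 1)``
  plus small thermal jitter;
* the inclusion follows a fraction ``alpha`` of that map (``alpha = 0`` for
  a rigid inclusion, which by definition also has zero conformational
  fluctuation; a flexible inclusion has ``alpha > 0`` plus seeded
  conformational jitter);
* each inclusion boundary bead is tied to one adjacent lipid bead by a
  breakable spring that detaches irreversibly the first frame its length
  exceeds its cohesive limit; the detached lipid bead then rides at the
  rest length (zero force), which keeps the static topology valid.

Because the inclusion's compliance divides the interface loading rate while
conformational fluctuation feeds the first-passage breaking test, a rigid
inclusion ruptures at a strictly smaller applied strain and a higher peak
interaction stress than its flexible counterpart — the orderings emerge
from the mechanism, not from per-variant thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .trajio import Box, FFParams, Frame, Topology
from .units import (KCAL_PER_MOL_A3_TO_MPA, KB_KCAL_PER_MOL_K,
                    thermal_velocity_sigma)

# ---------------------------------------------------------------------------
# file writers (LAMMPS dump / PSF / PRM)
# ---------------------------------------------------------------------------


def write_lammps_dump(frames: Sequence[Frame], path: str | Path,
                      unwrapped_columns: bool = True) -> None:
    """Write frames as a text LAMMPS dump (id type xu yu zu [v] [f])."""
    path = Path(path)
    with open(path, "w") as fh:
        for fr in frames:
            fh.write("ITEM: TIMESTEP\n%d\n" % fr.timestep)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % fr.n_atoms)
            flags = " ".join("pp" if p else "ff" for p in fr.box.periodic_flags)
            fh.write(f"ITEM: BOX BOUNDS {flags}\n")
            for lo, hi in zip(fr.box.lo, fr.box.hi):
                fh.write(f"{lo:.10g} {hi:.10g}\n")
            cols = ["id", "type"]
            cols += ["xu", "yu", "zu"] if unwrapped_columns else ["x", "y", "z"]
            if fr.velocities is not None:
                cols += ["vx", "vy", "vz"]
            if fr.forces is not None:
                cols += ["fx", "fy", "fz"]
            fh.write("ITEM: ATOMS " + " ".join(cols) + "\n")
            for k in range(fr.n_atoms):
                row = [str(fr.atom_ids[k]), str(fr.type_ids[k])]
                row += [f"{v:.17g}" for v in fr.positions[k]]
                if fr.velocities is not None:
                    row += [f"{v:.17g}" for v in fr.velocities[k]]
                if fr.forces is not None:
                    row += [f"{v:.17g}" for v in fr.forces[k]]
                fh.write(" ".join(row) + "\n")


def write_psf(topo: Topology, path: str | Path) -> None:
    """Write an X-PLOR-dialect PSF."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("PSF\n\n")
        fh.write("%8d !NTITLE\n REMARKS synthetic fixture topology\n\n" % 1)
        fh.write("%8d !NATOM\n" % topo.n_atoms)
        for k in range(topo.n_atoms):
            fh.write("%8d %-4s %-4d %-4s %-4s %-4s %10.6f %13.4f %11d\n" % (
                k + 1, topo.segment_names[k], topo.residue_ids[k],
                topo.residue_names[k], topo.atom_names[k],
                topo.atom_type_names[k], topo.charges[k], topo.masses[k], 0))
        fh.write("\n")

        def write_section(name: str, arr: np.ndarray, per_line: int) -> None:
            fh.write("%8d !%s\n" % (len(arr), name))
            flat = (arr + 1).ravel()
            width = arr.shape[1] if arr.size else 1
            per_row = per_line * width
            for start in range(0, len(flat), per_row):
                fh.write("".join("%8d" % v for v in flat[start:start + per_row]) + "\n")
            fh.write("\n")

        write_section("NBOND: bonds", topo.bonds, 4)
        write_section("NTHETA: angles", topo.angles, 3)
        write_section("NPHI: dihedrals", topo.dihedrals, 2)
        write_section("NIMPHI: impropers", topo.impropers, 2)


def write_prm(params: FFParams, path: str | Path) -> None:
    """Write a CHARMM parameter file covering the stored terms."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("* synthetic fixture parameters\n*\n\n")
        fh.write("BONDS\n")
        for (a, b), (k, r0) in sorted(params.bonds.items()):
            fh.write(f"{a:<6s} {b:<6s} {k:12.6f} {r0:12.6f}\n")
        fh.write("\nANGLES\n")
        for (a, b, c), (k, th0, kub, s0) in sorted(params.angles.items()):
            line = f"{a:<6s} {b:<6s} {c:<6s} {k:12.6f} {th0:12.6f}"
            if kub != 0.0:
                line += f" {kub:12.6f} {s0:12.6f}"
            fh.write(line + "\n")
        fh.write("\nDIHEDRALS\n")
        for (a, b, c, d), terms in sorted(params.dihedrals.items()):
            for n, (k, delta) in sorted(terms.items()):
                fh.write(f"{a:<6s} {b:<6s} {c:<6s} {d:<6s} "
                         f"{k:12.6f} {n:4d} {delta:12.6f}\n")
        fh.write("\nIMPROPER\n")
        for (a, b, c, d), (k, psi0) in sorted(params.impropers.items()):
            fh.write(f"{a:<6s} {b:<6s} {c:<6s} {d:<6s} "
                     f"{k:12.6f} {0:4d} {psi0:12.6f}\n")
        fh.write(f"\nNONBONDED cutnb {params.cutoff + 2.0:.3f} "
                 f"ctofnb {params.cutoff:.3f} ctonnb {params.switch_start:.3f}\n")
        for t, (eps, rmin_half, eps14, rmin14_half) in sorted(params.nonbonded.items()):
            fh.write(f"{t:<6s} 0.0 {-eps:12.6f} {rmin_half:12.6f} "
                     f"0.0 {-eps14:12.6f} {rmin14_half:12.6f}\n")
        fh.write("\nEND\n")


# ---------------------------------------------------------------------------
# affine trajectories
# ---------------------------------------------------------------------------


def make_affine_trajectory(n_atoms: int = 20,
                           F_schedule: Sequence[np.ndarray] | None = None,
                           translations: Sequence[np.ndarray] | None = None,
                           noise_sigma: float = 0.0,
                           seed: int = 0,
                           extent: float = 20.0
                           ) -> tuple[list[Frame], list[np.ndarray]]:
    """Point cloud moved by a schedule of affine maps, with ground truth.

    Positions are ``x_i(t) = F(t) X_i + c(t) + noise``; the returned ground
    truth is the F schedule itself.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if F_schedule is None:
        F_schedule = [np.eye(3)]
    F_schedule = [np.asarray(F, dtype=float) for F in F_schedule]
    for k, F in enumerate(F_schedule):
        if abs(np.linalg.det(F)) < 1e-12:
            raise ValidationError(f"singular deformation gradient at schedule step {k}")
    if translations is None:
        translations = [np.zeros(3)] * len(F_schedule)
    ref = rng.uniform(-extent / 2, extent / 2, size=(n_atoms, 3))
    box = Box(lo=[-10 * extent] * 3, hi=[10 * extent] * 3,
              periodic_flags=(False, False, False))
    frames = []
    for t, (F, c) in enumerate(zip(F_schedule, translations)):
        pos = ref @ F.T + np.asarray(c, dtype=float)
        if noise_sigma > 0:
            pos = pos + rng.normal(0.0, noise_sigma, size=pos.shape)
        frames.append(Frame(timestep=t, box=box,
                            atom_ids=np.arange(1, n_atoms + 1),
                            positions=pos,
                            type_ids=np.ones(n_atoms, dtype=np.int64)))
    return frames, F_schedule


def uniaxial_schedule(eps_max: float, n_frames: int, poisson: float = 0.0
                      ) -> list[np.ndarray]:
    """Linear ramp of uniaxial stretch along x with optional lateral contraction."""
    out = []
    for eps in np.linspace(0.0, eps_max, n_frames):
        out.append(np.diag([1.0 + eps, 1.0 - poisson * eps, 1.0 - poisson * eps]))
    return out


# ---------------------------------------------------------------------------
# toy systems with closed-form mechanics
# ---------------------------------------------------------------------------


@dataclass
class ToySystem:
    """A tiny system plus its analytically computed oracle values."""

    frame: Frame
    topo: Topology
    params: FFParams
    oracle: dict = field(default_factory=dict)

    def write(self, directory: str | Path, stem: str = "toy") -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"dump": directory / f"{stem}.dump",
                 "psf": directory / f"{stem}.psf",
                 "prm": directory / f"{stem}.prm",
                 "oracle": directory / f"{stem}.oracle.json"}
        write_lammps_dump([self.frame], paths["dump"])
        write_psf(self.topo, paths["psf"])
        write_prm(self.params, paths["prm"])
        with open(paths["oracle"], "w") as fh:
            json.dump(self.oracle, fh, indent=1)
        return paths


def _bare_topology(n: int, type_names: list[str], masses, charges=None,
                   bonds=(), angles=(), dihedrals=(), impropers=()) -> Topology:
    return Topology(masses=np.full(n, masses) if np.isscalar(masses) else masses,
                    charges=np.zeros(n) if charges is None else charges,
                    atom_type_names=type_names,
                    residue_ids=np.arange(1, n + 1),
                    residue_names=["RES"] * n,
                    segment_names=["SYN"] * n,
                    atom_names=[f"A{k+1}" for k in range(n)],
                    bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
                    angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
                    dihedrals=np.array(dihedrals, dtype=np.int64).reshape(-1, 4),
                    impropers=np.array(impropers, dtype=np.int64).reshape(-1, 4))


def _zero_eps_params(type_names: Sequence[str]) -> FFParams:
    p = FFParams()
    for t in set(type_names):
        p.nonbonded[t] = (0.0, 0.0, 0.0, 0.0)
    return p


def make_spring_dimer(k: float = 100.0, r0: float = 1.5, r: float = 2.0,
                      box_edge: float = 10.0) -> ToySystem:
    """Two bonded atoms stretched along x; closed-form virial stress.

    With ``E = k (b - b0)^2`` the bond tension is ``2 k (r - r0)`` and the
    tensile axial virial stress is ``r * 2k(r - r0) / V`` (kcal/mol/A^3).
    """
    box = Box(lo=[0, 0, 0], hi=[box_edge] * 3, periodic_flags=(False,) * 3)
    pos = np.array([[box_edge / 2 - r / 2, box_edge / 2, box_edge / 2],
                    [box_edge / 2 + r / 2, box_edge / 2, box_edge / 2]])
    frame = Frame(timestep=0, box=box, atom_ids=np.array([1, 2]),
                  positions=pos, type_ids=np.array([1, 1]),
                  velocities=np.zeros((2, 3)))
    topo = _bare_topology(2, ["SPR", "SPR"], 10.0, bonds=[(0, 1)])
    params = _zero_eps_params(["SPR"])
    params.bonds[("SPR", "SPR")] = (k, r0)
    v = box_edge ** 3
    sxx = r * 2.0 * k * (r - r0) / v
    return ToySystem(frame, topo, params, oracle={
        "volume_a3": v,
        "sigma_xx_kcal_mol_a3": sxx,
        "sigma_xx_mpa": sxx * KCAL_PER_MOL_A3_TO_MPA,
        "bond_force_kcal_mol_a": 2.0 * k * abs(r - r0)})


def make_lj_lattice(n_side: int = 4, eps: float = 0.2, rmin: float = 3.0
                    ) -> ToySystem:
    """Simple-cubic LJ lattice at spacing ``rmin``: force-free, zero virial.

    The cutoff is placed between the first (``rmin``) and second
    (``sqrt(2) rmin``) neighbour shells, and the switching region starts
    above ``rmin``, so every interacting pair sits exactly at the LJ
    minimum.
    """
    n = n_side ** 3
    grid = np.array([[i, j, k] for i in range(n_side)
                     for j in range(n_side) for k in range(n_side)], dtype=float)
    pos = grid * rmin + rmin
    edge = rmin * (n_side + 1)
    box = Box(lo=[0, 0, 0], hi=[edge] * 3, periodic_flags=(False,) * 3)
    frame = Frame(timestep=0, box=box, atom_ids=np.arange(1, n + 1),
                  positions=pos, type_ids=np.ones(n, dtype=np.int64),
                  velocities=np.zeros((n, 3)))
    topo = _bare_topology(n, ["LJA"] * n, 40.0)
    params = FFParams()
    params.nonbonded["LJA"] = (eps, rmin / 2, eps, rmin / 2)
    params.switch_start = rmin * 1.1
    params.cutoff = rmin * 1.3          # below sqrt(2) * rmin
    return ToySystem(frame, topo, params, oracle={
        "sigma_kcal_mol_a3": 0.0, "n_atoms": n})


def make_ideal_gas(n_atoms: int = 512, temperature_k: float = 310.0,
                   box_edge: float = 40.0, mass: float = 18.0,
                   seed: int = 0) -> ToySystem:
    """Non-interacting particles with Maxwell velocities; kinetic stress oracle.

    The oracle pressure is ``N k_B T / V`` (ideal-gas law).
    """
    rng = np.random.default_rng(seed)
    box = Box(lo=[0, 0, 0], hi=[box_edge] * 3)
    pos = rng.uniform(0.0, box_edge, size=(n_atoms, 3))
    vel = rng.normal(0.0, thermal_velocity_sigma(mass, temperature_k),
                     size=(n_atoms, 3))
    frame = Frame(timestep=0, box=box, atom_ids=np.arange(1, n_atoms + 1),
                  positions=pos, type_ids=np.ones(n_atoms, dtype=np.int64),
                  velocities=vel)
    topo = _bare_topology(n_atoms, ["GAS"] * n_atoms, mass)
    params = _zero_eps_params(["GAS"])
    v = box_edge ** 3
    p = n_atoms * KB_KCAL_PER_MOL_K * temperature_k / v
    return ToySystem(frame, topo, params, oracle={
        "pressure_kcal_mol_a3": p,
        "pressure_mpa": p * KCAL_PER_MOL_A3_TO_MPA,
        "temperature_k": temperature_k, "n_atoms": n_atoms})


def make_toy_system(kind: str, seed: int = 0, **kwargs) -> ToySystem:
    """Dispatch on ``kind`` in {spring_dimer, lj_lattice, ideal_gas}."""
    if kind == "spring_dimer":
        return make_spring_dimer(**kwargs)
    if kind == "lj_lattice":
        return make_lj_lattice(**kwargs)
    if kind == "ideal_gas":
        return make_ideal_gas(seed=seed, **kwargs)
    raise ValidationError(f"unknown toy-system kind {kind!r}")


# ---------------------------------------------------------------------------
# mock membrane under piston stretch
# ---------------------------------------------------------------------------


@dataclass
class MockMembraneRun:
    """Quasi-static mock membrane stretch with programmed cohesive failure."""

    frames: list[Frame]
    topo: Topology
    params: FFParams
    inclusion_ids: np.ndarray          # atom ids (1-based)
    lipid_ids: np.ndarray
    strain_schedule: np.ndarray        # applied axial strain per frame
    true_rupture_strain: float         # deterministic first-detach strain
    piston_l0: float                   # initial axial extent, A
    metadata: dict = field(default_factory=dict)

    def write(self, directory: str | Path, stem: str = "membrane"
              ) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"dump": directory / f"{stem}.dump",
                 "psf": directory / f"{stem}.psf",
                 "prm": directory / f"{stem}.prm",
                 "oracle": directory / f"{stem}.oracle.json"}
        write_lammps_dump(self.frames, paths["dump"])
        write_psf(self.topo, paths["psf"])
        write_prm(self.params, paths["prm"])
        with open(paths["oracle"], "w") as fh:
            json.dump({"true_rupture_strain": self.true_rupture_strain,
                       "strain_max": float(self.strain_schedule[-1]),
                       "n_frames": len(self.frames),
                       "piston_l0": self.piston_l0,
                       **self.metadata}, fh, indent=1)
        return paths


def make_mock_membrane_stretch(seed: int = 0,
                               rupture_strain: float = 0.12,
                               variant: str = "rigid",
                               failure_mode: str = "strain",
                               detach_length: float | None = None,
                               n_cells: int = 15,
                               spacing: float = 8.0,
                               inclusion_radius: float = 20.0,
                               eps_max: float = 0.3,
                               n_frames: int = 150,
                               poisson: float = 0.4,
                               alpha_flexible: float = 0.65,
                               k_lipid: float = 5.0,
                               k_inclusion: float = 50.0,
                               k_cohesive: float = 20.0,
                               thermal_jitter: float = 0.05,
                               conformational_jitter: float = 0.15,
                               piston_speed_m_s: float | None = None
                               ) -> MockMembraneRun:
    """Two-leaflet bead membrane with an embedded inclusion under stretch.

    ``variant`` is ``rigid`` (inclusion compliance 0, no conformational
    fluctuation) or ``flexible`` (compliance ``alpha_flexible`` plus seeded
    conformational jitter).  ``failure_mode='strain'`` programs every
    tensile cohesive bond to detach when the applied membrane strain
    reaches ``rupture_strain``; ``failure_mode='length'`` detaches a bond
    when its elongation exceeds the uniform ``detach_length`` (A) — the
    physical mode used for rigid/flexible comparisons.  Deterministic under
    a fixed seed.
    """
    if variant not in ("rigid", "flexible"):
        raise ValidationError(f"unknown inclusion variant {variant!r}")
    if failure_mode not in ("strain", "length"):
        raise ValidationError(f"unknown failure mode {failure_mode!r}")
    if failure_mode == "length" and (detach_length is None or detach_length <= 0):
        raise ValidationError("failure_mode='length' needs a positive detach_length")
    if failure_mode == "strain" and not (0.0 < rupture_strain < eps_max):
        raise ValidationError("programmed rupture strain must lie inside the ramp")
    half = spacing * (n_cells - 1) / 2.0
    if inclusion_radius >= half:
        raise ValidationError("inclusion radius must be smaller than the patch half-width")
    alpha = 0.0 if variant == "rigid" else alpha_flexible
    sig_inc = 0.0 if variant == "rigid" else conformational_jitter
    rng = np.random.default_rng(seed)

    # reference lattice, two leaflets, centered at the origin
    g = np.arange(n_cells) * spacing - half
    xy = np.array([(x, y) for x in g for y in g])
    ref = np.concatenate([np.column_stack([xy, np.full(len(xy), +10.0)]),
                          np.column_stack([xy, np.full(len(xy), -10.0)])])
    n = len(ref)
    r_inplane = np.hypot(ref[:, 0], ref[:, 1])
    is_inc = r_inplane <= inclusion_radius
    if not is_inc.any():
        raise ValidationError("inclusion radius selects no beads")

    # in-leaflet nearest-neighbour connectivity on the reference lattice
    def leaflet_neighbours() -> list[tuple[int, int]]:
        index = {(round(p[0], 6), round(p[1], 6), round(p[2], 6)): k
                 for k, p in enumerate(ref)}
        out = []
        for k, p in enumerate(ref):
            for dx, dy in ((spacing, 0.0), (0.0, spacing)):
                q = (round(p[0] + dx, 6), round(p[1] + dy, 6), round(p[2], 6))
                if q in index:
                    out.append((k, index[q]))
        return out

    neighbours = leaflet_neighbours()
    crossing = [(a, b) if is_inc[a] else (b, a)
                for a, b in neighbours if is_inc[a] != is_inc[b]]
    # cohesive zone: only boundary crossings along the loading axis carry
    # breakable springs, so the uniaxial load concentrates at the poles and
    # failure is a collective event rather than a smeared sequence
    crossing = [(i, l) for i, l in crossing
                if abs(ref[l, 0] - ref[i, 0]) > abs(ref[l, 1] - ref[i, 1])]
    if not crossing:
        raise ValidationError("no cohesive bonds cross the inclusion boundary")
    # one cohesive bond per lipid bead so detachment recoil is unambiguous
    used_lipids: set[int] = set()
    cohesive: list[tuple[int, int]] = []
    for inc, lip in crossing:
        if lip not in used_lipids:
            used_lipids.add(lip)
            cohesive.append((inc, lip))
    interface_lipids = np.array(sorted(used_lipids), dtype=np.int64)

    bonds = []
    for a, b in neighbours:
        if is_inc[a] and is_inc[b]:
            bonds.append((a, b))
        elif (not is_inc[a]) and (not is_inc[b]) \
                and a not in used_lipids and b not in used_lipids:
            bonds.append((a, b))
    cohesive_start = len(bonds)
    bonds.extend(cohesive)

    type_names = ["INC" if t else "LIP" for t in is_inc]
    topo = Topology(masses=np.full(n, 100.0), charges=np.zeros(n),
                    atom_type_names=type_names,
                    residue_ids=np.arange(1, n + 1),
                    residue_names=["MEM"] * n,
                    segment_names=["INCL" if t else "LIPD" for t in is_inc],
                    atom_names=[f"B{k+1}" for k in range(n)],
                    bonds=np.array(bonds, dtype=np.int64),
                    angles=np.empty((0, 3), dtype=np.int64),
                    dihedrals=np.empty((0, 4), dtype=np.int64),
                    impropers=np.empty((0, 4), dtype=np.int64))
    params = _zero_eps_params(["INC", "LIP"])
    params.bonds[FFParams._canon2("LIP", "LIP")] = (k_lipid, spacing)
    params.bonds[FFParams._canon2("INC", "INC")] = (k_inclusion, spacing)
    params.bonds[FFParams._canon2("INC", "LIP")] = (k_cohesive, spacing)

    eps_grid = np.linspace(0.0, eps_max, n_frames)

    def scheduled_positions(eps: float) -> np.ndarray:
        lip_map = np.array([1.0 + eps, 1.0 - poisson * eps, 1.0])
        inc_map = np.array([1.0 + alpha * eps, 1.0 - alpha * poisson * eps, 1.0])
        pos = ref * np.where(is_inc[:, None], inc_map, lip_map)
        return pos

    def scheduled_elongation(pair: tuple[int, int], eps: float) -> float:
        inc, lip = pair
        lip_map = np.array([1.0 + eps, 1.0 - poisson * eps, 1.0])
        inc_map = np.array([1.0 + alpha * eps, 1.0 - alpha * poisson * eps, 1.0])
        d = ref[lip] * lip_map - ref[inc] * inc_map
        return float(np.linalg.norm(d)) - spacing

    # cohesive limits per bond
    limits = np.full(len(cohesive), np.inf)
    if failure_mode == "strain":
        for k, pair in enumerate(cohesive):
            e_star = scheduled_elongation(pair, rupture_strain)
            e_end = scheduled_elongation(pair, eps_max)
            # only robustly tensile bonds are programmed to fail; weakly
            # loaded (lateral) bonds never detach and carry the residual
            if e_star > 0.25 and e_end > 1.2 * e_star:
                limits[k] = e_star
        if not np.isfinite(limits).any():
            raise ValidationError("no tensile cohesive bond reaches the "
                                  "programmed rupture strain; widen the ramp")
        true_rupture = float(rupture_strain)
    else:
        limits[:] = detach_length
        # deterministic first detachment: scan the schedule without jitter
        true_rupture = float("nan")
        fine = np.linspace(0.0, eps_max, 20 * n_frames)
        for k, pair in enumerate(cohesive):
            e = np.array([scheduled_elongation(pair, x) for x in fine])
            hit = np.nonzero(e > limits[k])[0]
            if hit.size:
                cand = float(fine[hit[0]])
                if not np.isfinite(true_rupture) or cand < true_rupture:
                    true_rupture = cand

    # synthesize frames with first-passage detachment bookkeeping
    box_pad = 4.0 * spacing
    extent = half + box_pad
    broken = np.zeros(len(cohesive), dtype=bool)
    frames: list[Frame] = []
    piston_l0 = 2.0 * half
    for t, eps in enumerate(eps_grid):
        # the box tracks the pistons: the axial extent grows with the ramp
        ext_x = half * (1.0 + eps) + box_pad
        box = Box(lo=[-ext_x, -extent, -extent], hi=[ext_x, extent, extent],
                  periodic_flags=(False, False, False))
        pos = scheduled_positions(eps)
        if thermal_jitter > 0:
            jitter = rng.normal(0.0, thermal_jitter, size=(n, 3))
            jitter[is_inc] = 0.0
            pos += jitter
        if sig_inc > 0:
            pos[is_inc] += rng.normal(0.0, sig_inc, size=(int(is_inc.sum()), 3))
        # first-passage detachment on instantaneous bond lengths
        for k, (inc, lip) in enumerate(cohesive):
            if broken[k]:
                continue
            if np.linalg.norm(pos[lip] - pos[inc]) - spacing > limits[k]:
                broken[k] = True
        # detached lipid beads ride at the rest length: zero cohesive force
        for k, (inc, lip) in enumerate(cohesive):
            if broken[k]:
                d = pos[lip] - pos[inc]
                nrm = np.linalg.norm(d)
                u = d / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                pos[lip] = pos[inc] + spacing * u
        frames.append(Frame(timestep=t, box=box,
                            atom_ids=np.arange(1, n + 1),
                            positions=pos.copy(),
                            type_ids=np.where(is_inc, 2, 1).astype(np.int64),
                            velocities=np.zeros((n, 3))))

    ids = np.arange(1, n + 1)
    meta = {"variant": variant, "failure_mode": failure_mode,
            "alpha": alpha, "seed": seed,
            "n_cohesive": len(cohesive),
            "n_breakable": int(np.isfinite(limits).sum()),
            "interface_lipid_ids": (interface_lipids + 1).tolist()}
    if piston_speed_m_s is not None:
        # engineering strain rate = v / L0; 1 m/s = 1e-5 A/fs
        meta["rate_per_s"] = piston_speed_m_s * 1e-5 / piston_l0 * 1e15
    return MockMembraneRun(frames=frames, topo=topo, params=params,
                           inclusion_ids=ids[is_inc], lipid_ids=ids[~is_inc],
                           strain_schedule=eps_grid,
                           true_rupture_strain=true_rupture,
                           piston_l0=piston_l0, metadata=meta)
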