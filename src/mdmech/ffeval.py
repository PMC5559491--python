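"""CHARMM additive force-field evaluation and pairwise force decomposition.

Implements the bonded terms (harmonic bonds ``E = k (b - b0)^2``, harmonic
angles with Urey-Bradley 1-3 springs, cosine dihedrals
``E = k (1 + cos(n phi - delta))``, harmonic impropers) and the nonbonded
terms (12-6 Lennard-Jones on ``Rmin`` form, cutoff Coulomb) with CHARMM
energy switching between ``switch_start`` and ``cutoff``.  Exclusions are
1-2 and 1-3; 1-4 pairs use the dedicated 1-4 LJ parameters when present
and a configurable electrostatic scale (1.0 by default, the additive
convention).  Long-range electrostatics (Ewald/PME) is deliberately not
offered: the stress extraction requires a well-defined pairwise
decomposition, which a mesh method does not have.

Every term is also decomposed into *central* pairwise forces (along the
interatomic axes among the term's atoms).  For 3- and 4-body terms the
decomposition solves a small linear system; because the per-atom forces of
any isolated term have zero resultant and zero torque, the system is
generically exactly determined, and a minimum-norm solution is used for
degenerate (collinear/planar-singular) geometries.  The central form makes
the pair set antisymmetric and torque-free, which the moment part of the
stress-equivalence principle requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, ValidationError
from .groups import AtomGroup, group_disjointness
from .trajio import FFParams, Frame, Topology
from .units import COULOMB_CONSTANT

logger = logging.getLogger(__name__)

TERM_NAMES = ("bond", "angle", "ub", "dihedral", "improper", "lj", "coulomb")

#: residual tolerance for the central-force decomposition, kcal/mol/A
DECOMP_TOL = 1e-8


@dataclass
class EnergyReport:
    """Per-term potential energies in kcal/mol."""

    terms: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


@dataclass
class PairForceSet:
    """Central pairwise force records for one frame.

    ``f_ij`` is the force exerted *on* atom ``i`` *by* atom ``j`` and is
    stored once per pair (``f_ji = -f_ij``); ``r_ij = x_i - x_j``.  Indices
    are 0-based rows of the frame the set was built from; ``atom_ids``
    carries the frame's id order so group membership can be resolved.
    """

    i: np.ndarray
    j: np.ndarray
    f_ij: np.ndarray
    r_ij: np.ndarray
    origin_term: np.ndarray          # indices into TERM_NAMES
    atom_ids: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    def per_atom_forces(self, n_atoms: int) -> np.ndarray:
        """Resultant per-atom forces implied by the pair list."""
        out = np.zeros((n_atoms, 3))
        np.add.at(out, self.i, self.f_ij)
        np.add.at(out, self.j, -self.f_ij)
        return out

    @classmethod
    def concatenate(cls, parts: Iterable["PairForceSet"],
                    atom_ids: np.ndarray) -> "PairForceSet":
        parts = [p for p in parts if p.n_pairs]
        if not parts:
            z = np.zeros(0, dtype=np.int64)
            return cls(z, z.copy(), np.zeros((0, 3)), np.zeros((0, 3)),
                       z.copy(), atom_ids)
        return cls(np.concatenate([p.i for p in parts]),
                   np.concatenate([p.j for p in parts]),
                   np.concatenate([p.f_ij for p in parts]),
                   np.concatenate([p.r_ij for p in parts]),
                   np.concatenate([p.origin_term for p in parts]),
                   atom_ids)


def _pairset(i, j, f, r, term: str, atom_ids) -> PairForceSet:
    i = np.asarray(i, dtype=np.int64)
    code = np.full(len(i), TERM_NAMES.index(term), dtype=np.int64)
    return PairForceSet(i, np.asarray(j, dtype=np.int64),
                        np.asarray(f, dtype=float).reshape(-1, 3),
                        np.asarray(r, dtype=float).reshape(-1, 3), code, atom_ids)


# ---------------------------------------------------------------------------
# central-force decomposition of multibody terms
# ---------------------------------------------------------------------------

def central_decompose(positions: np.ndarray, forces: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose per-atom forces of one m-body term into central pair forces.

    Returns ``(pair_index, coeffs, residual)`` where ``pair_index`` is an
    (npair, 2) array of local atom indices, ``coeffs[k]`` the signed scalar
    such that the force on atom a from atom b is
    ``coeffs * (x_a - x_b) / |x_a - x_b|``, and ``residual`` the per-atom
    reconstruction error.  Uses the minimum-norm least-squares solution,
    which is exact whenever the term's forces have zero net force and
    torque and the geometry is non-degenerate.
    """
    m = len(positions)
    pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
    npair = len(pairs)
    A = np.zeros((3 * m, npair))
    for k, (a, b) in enumerate(pairs):
        d = positions[a] - positions[b]
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue  # coincident atoms cannot carry a central force
        u = d / nrm
        A[3 * a:3 * a + 3, k] = u
        A[3 * b:3 * b + 3, k] = -u
    coeffs, *_ = np.linalg.lstsq(A, forces.ravel(), rcond=None)
    residual = (A @ coeffs - forces.ravel()).reshape(m, 3)
    return np.array(pairs, dtype=np.int64), coeffs, residual


def _decompose_terms(pos: np.ndarray, atom_idx: np.ndarray,
                     per_atom: np.ndarray, term: str,
                     atom_ids: np.ndarray) -> PairForceSet:
    """Run central decomposition over a batch of term instances.

    ``atom_idx`` is (nterm, m) frame rows; ``per_atom`` is (nterm, m, 3)
    analytic forces of each instance.
    """
    ii, jj, ff, rr = [], [], [], []
    for rows, f in zip(atom_idx, per_atom):
        p = pos[rows]
        pair_idx, coeffs, residual = central_decompose(p, f)
        if np.abs(residual).max() > DECOMP_TOL * max(1.0, np.abs(f).max()):
            raise ConsistencyError(
                f"{term} central-force decomposition residual "
                f"{np.abs(residual).max():.2e} exceeds tolerance")
        for (a, b), c in zip(pair_idx, coeffs):
            d = p[a] - p[b]
            nrm = np.linalg.norm(d)
            if nrm < 1e-12 or c == 0.0:
                continue
            ii.append(rows[a])
            jj.append(rows[b])
            ff.append(c * d / nrm)
            rr.append(d)
    if not ii:
        z = np.zeros(0, dtype=np.int64)
        return PairForceSet(z, z.copy(), np.zeros((0, 3)), np.zeros((0, 3)),
                            z.copy(), atom_ids)
    return _pairset(ii, jj, ff, rr, term, atom_ids)


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _bond_arrays(topo: Topology, params: FFParams,
                 idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = np.empty(len(idx))
    r0 = np.empty(len(idx))
    for m, (a, b) in enumerate(idx):
        k[m], r0[m] = params.bond_param(topo.atom_type_names[a], topo.atom_type_names[b])
    return k, r0


def _eval_bonds(pos, topo, params, atom_ids):
    idx = topo.bonds
    n = len(pos)
    forces = np.zeros((n, 3))
    if not len(idx):
        return forces, 0.0, _pairset([], [], [], [], "bond", atom_ids)
    k, r0 = _bond_arrays(topo, params, idx)
    d = pos[idx[:, 0]] - pos[idx[:, 1]]
    b = np.linalg.norm(d, axis=1)
    energy = float(np.sum(k * (b - r0) ** 2))
    # E = k (b - b0)^2  =>  |dE/db| = 2 k (b - b0)
    fmag = -2.0 * k * (b - r0) / b
    f = fmag[:, None] * d
    np.add.at(forces, idx[:, 0], f)
    np.add.at(forces, idx[:, 1], -f)
    return forces, energy, _pairset(idx[:, 0], idx[:, 1], f, d, "bond", atom_ids)


def _eval_angles(pos, topo, params, atom_ids):
    """Harmonic angles plus Urey-Bradley 1-3 springs."""
    idx = topo.angles
    n = len(pos)
    forces = np.zeros((n, 3))
    empty = _pairset([], [], [], [], "angle", atom_ids)
    if not len(idx):
        return forces, 0.0, 0.0, empty, empty
    ka = np.empty(len(idx))
    th0 = np.empty(len(idx))
    kub = np.empty(len(idx))
    s0 = np.empty(len(idx))
    for m, (a, b, c) in enumerate(idx):
        ka[m], th0[m], kub[m], s0[m] = params.angle_param(
            topo.atom_type_names[a], topo.atom_type_names[b], topo.atom_type_names[c])
    th0 = np.deg2rad(th0)

    r1 = pos[idx[:, 0]] - pos[idx[:, 1]]
    r2 = pos[idx[:, 2]] - pos[idx[:, 1]]
    n1 = np.linalg.norm(r1, axis=1)
    n2 = np.linalg.norm(r2, axis=1)
    cth = np.clip(np.einsum("ij,ij->i", r1, r2) / (n1 * n2), -1.0, 1.0)
    sth = np.sqrt(np.maximum(1.0 - cth ** 2, 1e-16))
    theta = np.arccos(cth)
    e_angle = float(np.sum(ka * (theta - th0) ** 2))

    a = -2.0 * ka * (theta - th0) / sth
    # at the collinear coordinate singularity the angle gradient is
    # undefined; the force is zeroed there (minimum-norm convention)
    a[sth < 1e-6] = 0.0
    a11 = a * cth / n1 ** 2
    a12 = -a / (n1 * n2)
    a22 = a * cth / n2 ** 2
    f1 = a11[:, None] * r1 + a12[:, None] * r2
    f3 = a22[:, None] * r2 + a12[:, None] * r1
    f2 = -f1 - f3
    np.add.at(forces, idx[:, 0], f1)
    np.add.at(forces, idx[:, 1], f2)
    np.add.at(forces, idx[:, 2], f3)
    per_atom = np.stack([f1, f2, f3], axis=1)
    angle_pairs = _decompose_terms(pos, idx, per_atom, "angle", atom_ids)

    # Urey-Bradley: harmonic spring between the 1-3 atoms
    e_ub = 0.0
    ub_pairs = _pairset([], [], [], [], "ub", atom_ids)
    has_ub = kub != 0.0
    if np.any(has_ub):
        iu = idx[has_ub]
        d = pos[iu[:, 0]] - pos[iu[:, 2]]
        s = np.linalg.norm(d, axis=1)
        e_ub = float(np.sum(kub[has_ub] * (s - s0[has_ub]) ** 2))
        fmag = -2.0 * kub[has_ub] * (s - s0[has_ub]) / s
        f = fmag[:, None] * d
        np.add.at(forces, iu[:, 0], f)
        np.add.at(forces, iu[:, 2], -f)
        ub_pairs = _pairset(iu[:, 0], iu[:, 2], f, d, "ub", atom_ids)
    return forces, e_angle, e_ub, angle_pairs, ub_pairs


def _dihedral_geometry(pos, idx):
    """Angles and gradients for torsion terms (atoms 1-2-3-4)."""
    b1 = pos[idx[:, 1]] - pos[idx[:, 0]]
    b2 = pos[idx[:, 2]] - pos[idx[:, 1]]
    b3 = pos[idx[:, 3]] - pos[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(np.einsum("ij,ij->i", np.cross(n1, n2), b2 / b2n[:, None]),
                     np.einsum("ij,ij->i", n1, n2))
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # planar-singular frames (three collinear atoms): torsion gradient is
    # undefined; zero the force there (minimum-norm convention)
    degenerate = (n1sq < 1e-12) | (n2sq < 1e-12)
    n1sq = np.where(degenerate, 1.0, n1sq)
    n2sq = np.where(degenerate, 1.0, n2sq)
    scale = np.where(degenerate, 0.0, 1.0)[:, None]
    dphi_d1 = -scale * (b2n / n1sq)[:, None] * n1
    dphi_d4 = scale * (b2n / n2sq)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
    dphi_d2 = -(1.0 + c12) * dphi_d1 + c32 * dphi_d4
    dphi_d3 = c12 * dphi_d1 - (1.0 + c32) * dphi_d4
    return phi, (dphi_d1, dphi_d2, dphi_d3, dphi_d4)


def _eval_torsions(pos, topo, params, atom_ids, improper: bool):
    idx = topo.impropers if improper else topo.dihedrals
    term = "improper" if improper else "dihedral"
    n = len(pos)
    forces = np.zeros((n, 3))
    if not len(idx):
        return forces, 0.0, _pairset([], [], [], [], term, atom_ids)
    phi, grads = _dihedral_geometry(pos, idx)
    energy = 0.0
    dE = np.zeros(len(idx))
    for m, rows in enumerate(idx):
        t = [topo.atom_type_names[a] for a in rows]
        if improper:
            k, psi0 = params.improper_param(*t)
            dpsi = phi[m] - np.deg2rad(psi0)
            dpsi -= 2.0 * np.pi * np.round(dpsi / (2.0 * np.pi))
            energy += k * dpsi ** 2
            dE[m] = 2.0 * k * dpsi
        else:
            for k, mult, delta in params.dihedral_terms(*t):
                energy += k * (1.0 + np.cos(mult * phi[m] - np.deg2rad(delta)))
                dE[m] += -k * mult * np.sin(mult * phi[m] - np.deg2rad(delta))
    per_atom = np.stack([-dE[:, None] * g for g in grads], axis=1)
    for a in range(4):
        np.add.at(forces, idx[:, a], per_atom[:, a])
    pairs = _decompose_terms(pos, idx, per_atom, term, atom_ids)
    return forces, float(energy), pairs


# ---------------------------------------------------------------------------
# nonbonded terms
# ---------------------------------------------------------------------------

def _exclusion_maps(topo: Topology) -> tuple[set, set]:
    """(excluded 1-2/1-3 pairs, 1-4 pairs), as sets of (min, max) tuples.

    A pair whose shortest bond path is 1 or 2 is excluded even if a ring
    also connects it in 3 steps.
    """
    adj: dict[int, set[int]] = {}
    for a, b in topo.bonds:
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    dist: dict[tuple[int, int], int] = {}
    for start in adj:
        seen = {start: 0}
        frontier = [start]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v, depth in seen.items():
            if v > start:
                key = (start, v)
                dist[key] = min(dist.get(key, 99), depth)
    excluded = {k for k, d in dist.items() if d <= 2}
    pairs14 = {k for k, d in dist.items() if d == 3}
    return excluded, pairs14


def _switching(r: np.ndarray, r_on: float, r_off: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM energy switching function S(r) and dS/dr."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    denom = (r_off ** 2 - r_on ** 2) ** 3
    mid = (r > r_on) & (r < r_off)
    rm = r[mid]
    a = r_off ** 2 - rm ** 2
    s[mid] = a ** 2 * (r_off ** 2 + 2.0 * rm ** 2 - 3.0 * r_on ** 2) / denom
    ds[mid] = 12.0 * rm * a * (r_on ** 2 - rm ** 2) / denom
    s[r >= r_off] = 0.0
    return s, ds


def _lj_coulomb(r, eps, rmin, qprod, dielectric, r_on, r_off):
    """Energies and radial force magnitudes (dV/dr sign included)."""
    s, ds = _switching(r, r_on, r_off)
    x = rmin / r
    v_lj = eps * (x ** 12 - 2.0 * x ** 6)
    dv_lj = eps * (-12.0 * x ** 12 + 12.0 * x ** 6) / r
    v_c = COULOMB_CONSTANT * qprod / (dielectric * r)
    dv_c = -v_c / r
    # switched force magnitude: -(d/dr)(S V) along r-hat
    return s * v_lj, -(ds * v_lj + s * dv_lj), s * v_c, -(ds * v_c + s * dv_c)


def _candidate_pairs(pos: np.ndarray, cutoff: float) -> np.ndarray:
    if len(pos) < 400:
        ii, jj = np.triu_indices(len(pos), k=1)
        d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        keep = d < cutoff
        return np.stack([ii[keep], jj[keep]], axis=1)
    tree = cKDTree(pos)
    return tree.query_pairs(cutoff, output_type="ndarray")


def _eval_nonbonded(pos, topo, params: FFParams, atom_ids):
    n = len(pos)
    forces = np.zeros((n, 3))
    empty = _pairset([], [], [], [], "lj", atom_ids)
    types = topo.atom_type_names
    used = set(types)
    params.validate_types(used)
    eps_t = {t: params.nonbonded[t][0] for t in used}
    if all(eps_t[t] == 0.0 for t in used) and np.all(topo.charges == 0.0):
        return forces, 0.0, 0.0, empty, _pairset([], [], [], [], "coulomb", atom_ids)

    excluded, pairs14 = _exclusion_maps(topo)
    cand = _candidate_pairs(pos, params.cutoff)
    if not len(cand):
        return forces, 0.0, 0.0, empty, _pairset([], [], [], [], "coulomb", atom_ids)
    keys = [(int(a), int(b)) for a, b in cand]
    keep = np.array([k not in excluded for k in keys])
    is14 = np.array([k in pairs14 for k in keys])
    cand, is14 = cand[keep], is14[keep]
    if not len(cand):
        return forces, 0.0, 0.0, empty, _pairset([], [], [], [], "coulomb", atom_ids)

    nb = np.array([params.nonbonded[t] for t in types])  # eps, rmin/2, eps14, rmin14/2
    ia, ja = cand[:, 0], cand[:, 1]
    eps = np.sqrt(nb[ia, 0] * nb[ja, 0])
    rmin = nb[ia, 1] + nb[ja, 1]
    eps14 = np.sqrt(nb[ia, 2] * nb[ja, 2])
    rmin14 = nb[ia, 3] + nb[ja, 3]
    eps = np.where(is14, eps14, eps)
    rmin = np.where(is14, rmin14, rmin)
    qprod = topo.charges[ia] * topo.charges[ja]
    qprod = np.where(is14, params.elec14_scale * qprod, qprod)

    d = pos[ia] - pos[ja]
    r = np.linalg.norm(d, axis=1)
    e_lj, f_lj, e_c, f_c = _lj_coulomb(
        r, eps, rmin, qprod, params.dielectric, params.switch_start, params.cutoff)
    u = d / r[:, None]
    flj_vec = f_lj[:, None] * u
    fc_vec = f_c[:, None] * u
    np.add.at(forces, ia, flj_vec + fc_vec)
    np.add.at(forces, ja, -(flj_vec + fc_vec))
    lj_pairs = _pairset(ia, ja, flj_vec, d, "lj", atom_ids)
    c_pairs = _pairset(ia, ja, fc_vec, d, "coulomb", atom_ids)
    return forces, float(e_lj.sum()), float(e_c.sum()), lj_pairs, c_pairs


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def evaluate_forces(frame: Frame, topo: Topology, params: FFParams
                    ) -> tuple[np.ndarray, EnergyReport]:
    """Per-atom forces (kcal/mol/A) and per-term energies for one frame."""
    pos = frame.positions
    ids = frame.atom_ids
    fb, eb, _ = _eval_bonds(pos, topo, params, ids)
    fa, ea, eub, _, _ = _eval_angles(pos, topo, params, ids)
    fd, ed, _ = _eval_torsions(pos, topo, params, ids, improper=False)
    fi, ei, _ = _eval_torsions(pos, topo, params, ids, improper=True)
    fn, elj, ec, _, _ = _eval_nonbonded(pos, topo, params, ids)
    report = EnergyReport(terms={"bond": eb, "angle": ea, "ub": eub,
                                 "dihedral": ed, "improper": ei,
                                 "lj": elj, "coulomb": ec})
    return fb + fa + fd + fi + fn, report


def pairwise_decompose(frame: Frame, topo: Topology, params: FFParams
                       ) -> PairForceSet:
    """Central pairwise decomposition of every force-field term.

    The per-term pairwise forces sum back to that term's per-atom forces
    (enforced to :data:`DECOMP_TOL`); pure pair terms (bonds, UB, LJ,
    Coulomb) decompose as themselves.
    """
    pos = frame.positions
    ids = frame.atom_ids
    _, _, bond_p = _eval_bonds(pos, topo, params, ids)
    _, _, _, ang_p, ub_p = _eval_angles(pos, topo, params, ids)
    _, _, dih_p = _eval_torsions(pos, topo, params, ids, improper=False)
    _, _, imp_p = _eval_torsions(pos, topo, params, ids, improper=True)
    _, _, _, lj_p, c_p = _eval_nonbonded(pos, topo, params, ids)
    return PairForceSet.concatenate([bond_p, ang_p, ub_p, dih_p, imp_p, lj_p, c_p], ids)


def cross_group_force(pairs: PairForceSet, a: AtomGroup, b: AtomGroup) -> np.ndarray:
    """Resultant force exerted by group ``b`` on group ``a`` (kcal/mol/A).

    Exactly antisymmetric under swapping the groups.  Groups must be
    disjoint.
    """
    disjoint, overlap = group_disjointness(a, b)
    if not disjoint:
        raise ValidationError(f"groups {a.name!r} and {b.name!r} overlap "
                              f"({len(overlap)} shared atoms)")
    ids_i = pairs.atom_ids[pairs.i]
    ids_j = pairs.atom_ids[pairs.j]
    in_a_i = np.isin(ids_i, a.atom_ids)
    in_a_j = np.isin(ids_j, a.atom_ids)
    in_b_i = np.isin(ids_i, b.atom_ids)
    in_b_j = np.isin(ids_j, b.atom_ids)
    fwd = in_a_i & in_b_j      # stored force acts on a-member
    rev = in_b_i & in_a_j      # stored force acts on b-member: negate
    return pairs.f_ij[fwd].sum(axis=0) - pairs.f_ij[rev].sum(axis=0)
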