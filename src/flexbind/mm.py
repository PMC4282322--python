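"""Gas-phase molecular-mechanics energies (no cutoff) and surface area.

Energies: Coulomb with k = 332.0716 kcal*A/(mol*e^2), 12-6 Lennard-Jones with
arithmetic rmin / geometric epsilon combining, harmonic bonds and angles,
cosine dihedrals and harmonic impropers.  Analytic gradients are provided for
all terms; they feed the minimizer and the finite-difference Hessian of the
entropy module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from flexbind.structure import Structure, Topology

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyComponents",
    "SurfaceResult",
    "NonpolarParams",
    "coulomb_energy",
    "lj_energy",
    "bonded_energy",
    "total_energy",
    "total_gradient",
    "surface_area",
    "nonpolar_solvation",
]

#: Coulomb constant in kcal*Angstrom / (mol * e^2).
COULOMB_CONSTANT = 332.0716

_MIN_R = 1e-6


@dataclass
class EnergyComponents:
    e_ele: float
    e_vdw: float
    e_int: float

    @property
    def e_mm(self) -> float:
        return self.e_ele + self.e_vdw + self.e_int


@dataclass
class SurfaceResult:
    per_atom: np.ndarray
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class NonpolarParams:
    """G_nonpolar = gamma * A + beta."""

    gamma: float = 0.00542   # kcal/mol/A^2
    beta: float = 0.92       # kcal/mol


def _pair_mask(n: int, excluded) -> np.ndarray:
    """Upper-triangle pair mask with excluded (i, j) pairs removed."""
    mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    for i, j in excluded:
        mask[min(i, j), max(i, j)] = False
    return mask


def _pair_distances(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    return diff, r


def coulomb_energy(coords: np.ndarray, charges: np.ndarray,
                   excluded=()) -> float:
    """Pairwise Coulomb energy over non-excluded pairs, no cutoff."""
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = coords.shape[0]
    if n < 2:
        return 0.0
    mask = _pair_mask(n, excluded)
    _, r = _pair_distances(coords)
    if np.any(r[mask] < _MIN_R):
        raise ValueError("overlapping atoms (r < 1e-6 A) in Coulomb sum")
    qq = charges[:, None] * charges[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(mask, qq / r, 0.0)
    return float(COULOMB_CONSTANT * e[mask].sum())


def lj_energy(coords: np.ndarray, rmin_half: np.ndarray, epsilon: np.ndarray,
              excluded=()) -> float:
    """12-6 Lennard-Jones energy: eps_ij * ((rmin_ij/r)^12 - 2 (rmin_ij/r)^6),
    rmin_ij = rmin_half_i + rmin_half_j, eps_ij = sqrt(eps_i * eps_j)."""
    coords = np.asarray(coords, dtype=float)
    rmin_half = np.asarray(rmin_half, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    n = coords.shape[0]
    if n < 2:
        return 0.0
    mask = _pair_mask(n, excluded)
    _, r = _pair_distances(coords)
    if np.any(r[mask] < _MIN_R):
        raise ValueError("overlapping atoms (r < 1e-6 A) in LJ sum")
    rmin = rmin_half[:, None] + rmin_half[None, :]
    eps = np.sqrt(epsilon[:, None] * epsilon[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = np.where(mask, (rmin / r) ** 6, 0.0)
    e = eps * (x6 ** 2 - 2.0 * x6)
    return float(e[mask].sum())


def _angle_rad(coords, i, j, k):
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return np.arccos(cosang), u, v, nu, nv, cosang


def _dihedral_rad(coords, i, j, k, l):
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(np.cross(n1, n2) @ b2 / nb2, n1 @ n2)
    return phi, b1, b2, b3, n1, n2, nb2


def _topo_arrays(topology: Topology) -> dict[str, np.ndarray]:
    """Cache the bonded-term index/parameter arrays on the topology."""
    cached = getattr(topology, "_mm_arrays", None)
    if cached is not None:
        return cached
    arrays = {
        "bonds": np.array(topology.bonds, dtype=float).reshape(-1, 4),
        "angles": np.array(topology.angles, dtype=float).reshape(-1, 5),
        "dihedrals": np.array(topology.dihedrals, dtype=float).reshape(-1, 7),
        "impropers": np.array(topology.impropers, dtype=float).reshape(-1, 6),
    }
    topology._mm_arrays = arrays
    return arrays


def _angles_vec(coords, arr):
    i = arr[:, 0].astype(int)
    j = arr[:, 1].astype(int)
    k = arr[:, 2].astype(int)
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
    sin2 = 1.0 - cosang ** 2
    if np.any(sin2 < 1e-12):
        bad = int(np.argmax(sin2 < 1e-12))
        raise ValueError(
            f"undefined angle for collinear triple ({i[bad]},{j[bad]},{k[bad]})")
    theta = np.arccos(cosang)
    return i, j, k, u, v, nu, nv, cosang, np.sqrt(sin2), theta


def _torsions_vec(coords, idx4):
    i, j, k, l = (idx4[:, c].astype(int) for c in range(4))
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    phi = np.arctan2((np.cross(n1, n2) * b2).sum(axis=1) / nb2,
                     (n1 * n2).sum(axis=1))
    return i, j, k, l, b1, b2, b3, n1, n2, nb2, phi


def bonded_energy(topology: Topology, coords: np.ndarray
                  ) -> dict[str, float]:
    """Internal energy broken down by term.

    Harmonic bonds ``k (b - b0)^2``; harmonic angles ``k (theta - theta0)^2``
    with the deviation in radians; dihedrals ``k (1 + cos(n phi - delta))``;
    harmonic impropers ``k (psi - psi0)^2``.
    """
    coords = np.asarray(coords, dtype=float)
    arr = _topo_arrays(topology)

    e_bond = 0.0
    if arr["bonds"].size:
        i = arr["bonds"][:, 0].astype(int)
        j = arr["bonds"][:, 1].astype(int)
        b = np.linalg.norm(coords[i] - coords[j], axis=1)
        e_bond = (arr["bonds"][:, 2] * (b - arr["bonds"][:, 3]) ** 2).sum()

    e_angle = 0.0
    if arr["angles"].size:
        *_, theta = _angles_vec(coords, arr["angles"])
        e_angle = (arr["angles"][:, 3]
                   * (theta - np.radians(arr["angles"][:, 4])) ** 2).sum()

    e_dihedral = 0.0
    if arr["dihedrals"].size:
        *_, phi = _torsions_vec(coords, arr["dihedrals"][:, :4])
        kd = arr["dihedrals"][:, 4]
        n = arr["dihedrals"][:, 5]
        delta = np.radians(arr["dihedrals"][:, 6])
        e_dihedral = (kd * (1.0 + np.cos(n * phi - delta))).sum()

    e_improper = 0.0
    if arr["impropers"].size:
        *_, psi = _torsions_vec(coords, arr["impropers"][:, :4])
        dpsi = psi - np.radians(arr["impropers"][:, 5])
        dpsi = np.arctan2(np.sin(dpsi), np.cos(dpsi))  # wrap to (-pi, pi]
        e_improper = (arr["impropers"][:, 4] * dpsi ** 2).sum()

    total = e_bond + e_angle + e_dihedral + e_improper
    return {"bond": float(e_bond), "angle": float(e_angle),
            "dihedral": float(e_dihedral), "improper": float(e_improper),
            "total": float(total)}


def total_energy(structure: Structure, topology: Topology,
                 coords: np.ndarray | None = None) -> EnergyComponents:
    """E_MM = E_ele + E_vdW + E_int on a parameterized structure."""
    if coords is None:
        coords = structure.coords
    e_ele = coulomb_energy(coords, structure.charges, topology.excluded)
    rmin_half = np.array([a.lj_rmin_half for a in structure.atoms])
    epsilon = np.array([a.lj_epsilon for a in structure.atoms])
    e_vdw = lj_energy(coords, rmin_half, epsilon, topology.excluded)
    e_int = bonded_energy(topology, coords)["total"]
    return EnergyComponents(e_ele=e_ele, e_vdw=e_vdw, e_int=e_int)


# ---------------------------------------------------------------------------
# Analytic gradient
# ---------------------------------------------------------------------------

def total_gradient(structure: Structure, topology: Topology,
                   coords: np.ndarray | None = None) -> np.ndarray:
    """Analytic gradient dE/dx of the total MM energy, shape (n, 3)."""
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    grad = np.zeros((n, 3))

    charges = structure.charges
    rmin_half = np.array([a.lj_rmin_half for a in structure.atoms])
    epsilon = np.array([a.lj_epsilon for a in structure.atoms])

    if n >= 2:
        mask = _pair_mask(n, topology.excluded)
        diff, r = _pair_distances(coords)
        rs = np.where(mask, r, 1.0)
        # Coulomb: dE/dr = -k q_i q_j / r^2
        qq = charges[:, None] * charges[None, :]
        dEdr = -COULOMB_CONSTANT * qq / rs ** 2
        # LJ: E = eps (x^12 - 2 x^6), x = rmin/r; dE/dr = -12 eps (x^12 - x^6)/r
        rmin = rmin_half[:, None] + rmin_half[None, :]
        eps = np.sqrt(epsilon[:, None] * epsilon[None, :])
        x6 = (rmin / rs) ** 6
        dEdr = dEdr - 12.0 * eps * (x6 ** 2 - x6) / rs
        dEdr = np.where(mask, dEdr, 0.0)
        # unit vector from j to i is diff/r; force on i along +diff for dEdr<0
        with np.errstate(invalid="ignore"):
            per_pair = dEdr[:, :, None] * diff / rs[:, :, None]
        grad += per_pair.sum(axis=1)
        grad -= per_pair.sum(axis=0)

    arr = _topo_arrays(topology)

    if arr["bonds"].size:
        i = arr["bonds"][:, 0].astype(int)
        j = arr["bonds"][:, 1].astype(int)
        d = coords[i] - coords[j]
        b = np.linalg.norm(d, axis=1)
        if np.any(b < _MIN_R):
            bad = int(np.argmax(b < _MIN_R))
            raise ValueError(f"zero-length bond ({i[bad]},{j[bad]})")
        g = (2.0 * arr["bonds"][:, 2] * (b - arr["bonds"][:, 3]) / b)[:, None] * d
        np.add.at(grad, i, g)
        np.add.at(grad, j, -g)

    if arr["angles"].size:
        i, j, k, u, v, nu, nv, cosang, sintheta, theta = _angles_vec(
            coords, arr["angles"])
        nu = nu[:, None]
        nv = nv[:, None]
        cs = cosang[:, None]
        st = sintheta[:, None]
        dtheta_di = -(v / (nu * nv) - cs * u / nu ** 2) / st
        dtheta_dk = -(u / (nu * nv) - cs * v / nv ** 2) / st
        pref = (2.0 * arr["angles"][:, 3]
                * (theta - np.radians(arr["angles"][:, 4])))[:, None]
        np.add.at(grad, i, pref * dtheta_di)
        np.add.at(grad, k, pref * dtheta_dk)
        np.add.at(grad, j, -pref * (dtheta_di + dtheta_dk))

    def add_torsion_grads(idx4, dEdphi):
        i, j, k, l, b1, b2, b3, n1, n2, nb2, phi = _torsions_vec(coords, idx4)
        n1sq = (n1 ** 2).sum(axis=1)
        n2sq = (n2 ** 2).sum(axis=1)
        if np.any(n1sq < 1e-12) or np.any(n2sq < 1e-12):
            bad = int(np.argmax((n1sq < 1e-12) | (n2sq < 1e-12)))
            raise ValueError(f"degenerate torsion ({i[bad]},{j[bad]},"
                             f"{k[bad]},{l[bad]})")
        dphi_di = (-nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        p = ((b1 * b2).sum(axis=1) / nb2 ** 2)[:, None]
        q = ((b3 * b2).sum(axis=1) / nb2 ** 2)[:, None]
        dphi_dj = -(1.0 + p) * dphi_di + q * dphi_dl
        dphi_dk = p * dphi_di - (1.0 + q) * dphi_dl
        w = dEdphi[:, None]
        np.add.at(grad, i, w * dphi_di)
        np.add.at(grad, j, w * dphi_dj)
        np.add.at(grad, k, w * dphi_dk)
        np.add.at(grad, l, w * dphi_dl)

    if arr["dihedrals"].size:
        *_, phi = _torsions_vec(coords, arr["dihedrals"][:, :4])
        kd = arr["dihedrals"][:, 4]
        n = arr["dihedrals"][:, 5]
        delta = np.radians(arr["dihedrals"][:, 6])
        add_torsion_grads(arr["dihedrals"][:, :4], -kd * n * np.sin(n * phi - delta))

    if arr["impropers"].size:
        *_, psi = _torsions_vec(coords, arr["impropers"][:, :4])
        dpsi = psi - np.radians(arr["impropers"][:, 5])
        dpsi = np.arctan2(np.sin(dpsi), np.cos(dpsi))
        add_torsion_grads(arr["impropers"][:, :4], 2.0 * arr["impropers"][:, 4] * dpsi)

    return grad


def _nb_cache(structure: Structure, topology: Topology) -> dict[str, np.ndarray]:
    """Static pairwise matrices (mask, k*qq, eps_ij, rmin_ij) cached on the
    topology; valid as long as the parameter assignment does not change."""
    cached = getattr(topology, "_nb_cache", None)
    if cached is not None and cached["n"] == len(structure):
        return cached
    n = len(structure)
    mask = _pair_mask(n, topology.excluded)
    charges = structure.charges
    rmin_half = np.array([a.lj_rmin_half for a in structure.atoms])
    epsilon = np.array([a.lj_epsilon for a in structure.atoms])
    cached = {
        "n": n,
        "mask": mask,
        "kqq": np.where(mask, COULOMB_CONSTANT * charges[:, None] * charges[None, :], 0.0),
        "eps": np.where(mask, np.sqrt(epsilon[:, None] * epsilon[None, :]), 0.0),
        "rmin": rmin_half[:, None] + rmin_half[None, :],
    }
    topology._nb_cache = cached
    return cached


def energy_and_gradient(structure: Structure, topology: Topology,
                        coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Fused E_MM and gradient evaluation (single pairwise pass); the hot path
    for minimization and Hessian builds."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    cache = _nb_cache(structure, topology)
    grad = np.zeros((n, 3))
    e_nb = 0.0
    if n >= 2:
        mask = cache["mask"]
        diff, r = _pair_distances(coords)
        rs = np.where(mask, r, 1.0)
        inv_r = 1.0 / rs
        e_c = cache["kqq"] * inv_r
        x6 = np.where(mask, (cache["rmin"] * inv_r) ** 6, 0.0)
        e_lj = cache["eps"] * (x6 ** 2 - 2.0 * x6)
        e_nb = float(e_c[mask].sum() + e_lj[mask].sum())
        dEdr = -e_c * inv_r - 12.0 * cache["eps"] * (x6 ** 2 - x6) * inv_r
        per_pair = (dEdr * inv_r)[:, :, None] * diff
        grad += per_pair.sum(axis=1)
        grad -= per_pair.sum(axis=0)
    e_int = _bonded_energy_gradient(topology, coords, grad)
    return e_nb + e_int, grad


def _bonded_energy_gradient(topology: Topology, coords: np.ndarray,
                            grad: np.ndarray) -> float:
    """Accumulate bonded gradient into ``grad``; return bonded energy."""
    arr = _topo_arrays(topology)
    e = 0.0
    if arr["bonds"].size:
        i = arr["bonds"][:, 0].astype(int)
        j = arr["bonds"][:, 1].astype(int)
        d = coords[i] - coords[j]
        b = np.linalg.norm(d, axis=1)
        db = b - arr["bonds"][:, 3]
        e += float((arr["bonds"][:, 2] * db ** 2).sum())
        g = (2.0 * arr["bonds"][:, 2] * db / b)[:, None] * d
        np.add.at(grad, i, g)
        np.add.at(grad, j, -g)
    if arr["angles"].size:
        i, j, k, u, v, nu, nv, cosang, sintheta, theta = _angles_vec(
            coords, arr["angles"])
        dth = theta - np.radians(arr["angles"][:, 4])
        e += float((arr["angles"][:, 3] * dth ** 2).sum())
        nu = nu[:, None]
        nv = nv[:, None]
        cs = cosang[:, None]
        st = sintheta[:, None]
        dtheta_di = -(v / (nu * nv) - cs * u / nu ** 2) / st
        dtheta_dk = -(u / (nu * nv) - cs * v / nv ** 2) / st
        pref = (2.0 * arr["angles"][:, 3] * dth)[:, None]
        np.add.at(grad, i, pref * dtheta_di)
        np.add.at(grad, k, pref * dtheta_dk)
        np.add.at(grad, j, -pref * (dtheta_di + dtheta_dk))

    def torsion(idx4, efun, dfun):
        nonlocal e
        i, j, k, l, b1, b2, b3, n1, n2, nb2, phi = _torsions_vec(coords, idx4)
        e += float(efun(phi).sum())
        dEdphi = dfun(phi)
        n1sq = (n1 ** 2).sum(axis=1)
        n2sq = (n2 ** 2).sum(axis=1)
        dphi_di = (-nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        p = ((b1 * b2).sum(axis=1) / nb2 ** 2)[:, None]
        q = ((b3 * b2).sum(axis=1) / nb2 ** 2)[:, None]
        dphi_dj = -(1.0 + p) * dphi_di + q * dphi_dl
        dphi_dk = p * dphi_di - (1.0 + q) * dphi_dl
        w = dEdphi[:, None]
        np.add.at(grad, i, w * dphi_di)
        np.add.at(grad, j, w * dphi_dj)
        np.add.at(grad, k, w * dphi_dk)
        np.add.at(grad, l, w * dphi_dl)

    if arr["dihedrals"].size:
        kd = arr["dihedrals"][:, 4]
        nm = arr["dihedrals"][:, 5]
        dl = np.radians(arr["dihedrals"][:, 6])
        torsion(arr["dihedrals"][:, :4],
                lambda phi: kd * (1.0 + np.cos(nm * phi - dl)),
                lambda phi: -kd * nm * np.sin(nm * phi - dl))
    if arr["impropers"].size:
        kp = arr["impropers"][:, 4]
        p0 = np.radians(arr["impropers"][:, 5])

        def wrap(phi):
            d = phi - p0
            return np.arctan2(np.sin(d), np.cos(d))

        torsion(arr["impropers"][:, :4],
                lambda phi: kp * wrap(phi) ** 2,
                lambda phi: 2.0 * kp * wrap(phi))
    return e


# ---------------------------------------------------------------------------
# Surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def surface_area(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                 n_points: int = 960) -> SurfaceResult:
    """Solvent-accessible surface by deterministic Shrake-Rupley sampling.

    Atoms with zero radius are excluded (with a warning) from both the surface
    and the occlusion test.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    active = radii > 0
    if not np.all(active):
        warnings.warn(f"{int((~active).sum())} zero-radius atoms excluded "
                      "from surface computation", stacklevel=2)
    pts = _sphere_points(n_points)
    ext = radii + probe
    per_atom = np.zeros(n)
    act_idx = np.where(active)[0]
    for i in act_idx:
        ri = ext[i]
        # candidate occluders
        d = np.linalg.norm(coords[act_idx] - coords[i], axis=1)
        nbr = act_idx[(d < ri + ext[act_idx]) & (act_idx != i)]
        sample = coords[i] + ri * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in nbr:
            dj = np.linalg.norm(sample - coords[j], axis=1)
            exposed &= dj >= ext[j]
        per_atom[i] = 4.0 * np.pi * ri ** 2 * exposed.mean()
    return SurfaceResult(per_atom=per_atom, probe=probe, n_points=n_points)


def nonpolar_solvation(area: float, params: NonpolarParams | None = None) -> float:
    """G_nonpolar = gamma * A + beta (kcal/mol)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    if params is None:
        params = NonpolarParams()
    return params.gamma * area + params.beta
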