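"""Deterministic, seeded fixture generators.

Everything the test surface needs is built here: a two-domain receptor with an
engineered-disulfide domain and a bound tripeptide ligand (full mini force
field), hinge-bending ensembles with prescribed angle distributions, module
chains on arcs of known curvature, and Born ions for PB validation.

The mini force field is united-atom (heavy atoms only) and entirely
self-contained; it makes no claim of realism beyond topological shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flexbind.geometry import AnchorPair, interdomain_angle
from flexbind.structure import (Atom, ParameterSet, Structure, Topology,
                                Trajectory, assign_parameters)

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "HingeTrajectorySpec",
    "ModuleChainSpec",
    "BornSystemSpec",
    "mini_forcefield",
    "make_toy_complex",
    "make_hinge_trajectory",
    "make_module_chain",
    "make_born_system",
    "make_ensemble",
]


# ---------------------------------------------------------------------------
# Mini force field
# ---------------------------------------------------------------------------

_BB = {  # name -> (element, charge, mass, pb_radius, rmin_half, epsilon)
    "N": ("N", -0.40, 14.007, 1.70, 1.85, 0.17),
    "CA": ("C", 0.30, 12.011, 2.00, 2.00, 0.08),
    "C": ("C", 0.50, 12.011, 2.00, 2.00, 0.08),
    "O": ("O", -0.40, 15.999, 1.60, 1.70, 0.12),
}

_SIDE = {
    "GLY": {},
    "ALA": {"CB": ("C", 0.00, 12.011, 2.00, 2.00, 0.08)},
    "CYS": {"CB": ("C", 0.10, 12.011, 2.00, 2.00, 0.08),
            "SG": ("S", -0.10, 32.06, 2.00, 2.00, 0.30)},
    "LEU": {"CB": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CG": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CD1": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CD2": ("C", 0.00, 12.011, 2.00, 2.00, 0.08)},
    "ASP": {"CB": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CG": ("C", 0.60, 12.011, 2.00, 2.00, 0.08),
            "OD1": ("O", -0.80, 15.999, 1.60, 1.70, 0.12),
            "OD2": ("O", -0.80, 15.999, 1.60, 1.70, 0.12)},
    "LYS": {"CB": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CG": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CD": ("C", 0.00, 12.011, 2.00, 2.00, 0.08),
            "CE": ("C", 0.20, 12.011, 2.00, 2.00, 0.08),
            "NZ": ("N", 0.80, 14.007, 1.70, 1.85, 0.17)},
}

_SIDE_BONDS = {
    "ALA": [("CA", "CB", 280.0, 1.53)],
    "CYS": [("CA", "CB", 280.0, 1.53), ("CB", "SG", 240.0, 1.81)],
    "LEU": [("CA", "CB", 280.0, 1.53), ("CB", "CG", 280.0, 1.53),
            ("CG", "CD1", 280.0, 1.53), ("CG", "CD2", 280.0, 1.53)],
    "ASP": [("CA", "CB", 280.0, 1.53), ("CB", "CG", 280.0, 1.53),
            ("CG", "OD1", 450.0, 1.25), ("CG", "OD2", 450.0, 1.25)],
    "LYS": [("CA", "CB", 280.0, 1.53), ("CB", "CG", 280.0, 1.53),
            ("CG", "CD", 280.0, 1.53), ("CD", "CE", 280.0, 1.53),
            ("CE", "NZ", 280.0, 1.48)],
    "GLY": [],
}


def mini_forcefield() -> ParameterSet:
    """The bundled united-atom parameter set covering GLY/ALA/CYS/LEU/ASP/LYS
    plus the single-atom Born ion residue ION."""
    ps = ParameterSet()
    for resname in _SIDE:
        for name, vals in {**_BB, **_SIDE[resname]}.items():
            ps.atoms[(resname, name)] = vals
        for a1, a2, k, b0 in [("N", "CA", 300.0, 1.46), ("CA", "C", 300.0, 1.52),
                              ("C", "O", 500.0, 1.23)] + _SIDE_BONDS[resname]:
            lo, hi = sorted((a1, a2))
            ps.bonds[(resname, lo, hi)] = (k, b0)
    ps.atoms[("ION", "ION")] = ("X", 1.0, 22.99, 2.0, 2.0, 0.1)
    ps.links.append(("C", "N", 350.0, 1.33))
    ps.crosses.append(("SG", "SG", 120.0, 2.05, 2.5))
    ps.angles["*"] = (50.0, 111.0)
    ps.dihedrals[("*", "*")] = (0.15, 3.0, 0.0)
    for resname in _SIDE:
        ps.impropers[resname] = [("N", "CA", "C", "O", 0.5, 0.0)]
    return ps


# ---------------------------------------------------------------------------
# Chain builder
# ---------------------------------------------------------------------------

_ZIG = np.radians(34.5)   # gives 111 deg between consecutive bond directions


def _chain_atoms(sequence, chain: str, start: np.ndarray,
                 resid_start: int = 1, cys_up: bool = True) -> list[Atom]:
    """Build a zig-zag heavy-atom peptide chain in the xy-plane, side chains
    along +/-z (cysteines forced +z so engineered bridges can close)."""
    u_a = np.array([np.cos(_ZIG), np.sin(_ZIG), 0.0])
    u_b = np.array([np.cos(_ZIG), -np.sin(_ZIG), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])

    atoms: list[Atom] = []
    pos_n = np.array(start, dtype=float)
    toggle = True  # True -> next bond along u_a

    def step(length):
        nonlocal toggle
        d = u_a if toggle else u_b
        toggle = not toggle
        return length * d

    for r, resname in enumerate(sequence):
        resid = resid_start + r
        ca = pos_n + step(1.46)
        d_cac = step(1.52)
        cc = ca + d_cac
        # carbonyl O along the external bisector of the CA->C and C->N' bonds
        u_next = u_a if toggle else u_b
        o_dir = d_cac / np.linalg.norm(d_cac) - u_next
        o = cc + 1.23 * o_dir / np.linalg.norm(o_dir)
        here = [("N", pos_n), ("CA", ca), ("C", cc), ("O", o)]

        sz = z if (resname == "CYS" and cys_up) else (z if r % 2 == 0 else -z)
        if resname != "GLY":
            cb = ca + 1.53 * sz
            here.append(("CB", cb))
            if resname == "CYS":
                here.append(("SG", cb + 1.81 * sz))
            elif resname == "LEU":
                cg = cb + 1.53 * sz
                here.append(("CG", cg))
                here.append(("CD1", cg + 1.53 * (0.6 * sz + 0.8 * x) / np.linalg.norm(0.6 * sz + 0.8 * x)))
                here.append(("CD2", cg + 1.53 * (0.6 * sz - 0.8 * x) / np.linalg.norm(0.6 * sz - 0.8 * x)))
            elif resname == "ASP":
                cg = cb + 1.53 * sz
                here.append(("CG", cg))
                here.append(("OD1", cg + 1.25 * (0.6 * sz + 0.8 * x) / np.linalg.norm(0.6 * sz + 0.8 * x)))
                here.append(("OD2", cg + 1.25 * (0.6 * sz - 0.8 * x) / np.linalg.norm(0.6 * sz - 0.8 * x)))
            elif resname == "LYS":
                cg = cb + 1.53 * sz
                cd = cg + 1.53 * (0.9 * sz + 0.44 * x) / np.linalg.norm(0.9 * sz + 0.44 * x)
                ce = cd + 1.53 * (0.9 * sz - 0.44 * x) / np.linalg.norm(0.9 * sz - 0.44 * x)
                here.append(("CG", cg))
                here.append(("CD", cd))
                here.append(("CE", ce))
                here.append(("NZ", ce + 1.48 * sz))
        for name, xyz in here:
            el = (_SIDE[resname].get(name) or _BB.get(name))[0]
            atoms.append(Atom(name=name, element=el, resname=resname,
                              resid=resid, chain=chain, xyz=np.array(xyz)))
        pos_n = cc + step(1.33)
    return atoms


def _close_disulfide(atoms: list[Atom], chain: str, r1: int, r2: int) -> None:
    """Reposition the two SG atoms so the bridge closes at ~2.05 A with exact
    CB-SG bond lengths."""
    def find(resid, name):
        for a in atoms:
            if a.chain == chain and a.resid == resid and a.name == name:
                return a
        raise ValueError(f"missing {name} in residue {resid}")

    cb1, cb2 = find(r1, "CB"), find(r2, "CB")
    sg1, sg2 = find(r1, "SG"), find(r2, "SG")
    d = cb2.xyz - cb1.xyz
    dist = np.linalg.norm(d)
    u = d / dist
    a = (dist - 2.05) / 2.0
    if abs(a) >= 1.81:
        raise ValueError(f"cysteines {r1}/{r2} too far apart to bridge")
    h = np.sqrt(1.81 ** 2 - a ** 2)
    zhat = np.array([0.0, 0.0, 1.0])
    perp = zhat - (zhat @ u) * u
    perp = perp / np.linalg.norm(perp)
    sg1.xyz = cb1.xyz + a * u + h * perp
    sg2.xyz = cb2.xyz - a * u + h * perp


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    domain1_sequence: tuple[str, ...] = ("GLY", "ALA", "CYS", "CYS", "ASP",
                                         "CYS", "CYS", "LEU", "ALA")
    hinge_sequence: tuple[str, ...] = ("GLY", "GLY")
    domain2_sequence: tuple[str, ...] = ("ALA", "LEU", "ALA", "GLY", "ALA",
                                         "LEU", "ALA", "GLY", "ALA")
    ligand_sequence: tuple[str, ...] = ("LEU", "ALA", "LYS")
    disulfide_pairs: tuple[tuple[int, int], ...] = ((3, 4), (6, 7))
    base_angle: float = 100.0      # initial domain-2 rotation about the hinge, deg
    ligand_offset: tuple[float, float, float] = (4.0, 6.5, 0.0)
    jitter: float = 0.02           # A, symmetry-breaking noise
    seed: int = 0


@dataclass
class ToyComplex:
    structure: Structure
    topology: Topology
    params: ParameterSet
    anchors: AnchorPair
    receptor_indices: list[int]
    ligand_indices: list[int]
    domain2_first_resid: int
    pivot_index: int               # hinge CA about which domain 2 rotates

    @property
    def base_angle(self) -> float:
        return interdomain_angle(self.structure, self.anchors)


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def make_toy_complex(spec: ToyComplexSpec | None = None
                     ) -> ToyComplex:
    """Two rigid mini-domains joined by a hinge, with engineered disulfides in
    domain 1 and a tripeptide ligand in contact with domain 1."""
    if spec is None:
        spec = ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    params = mini_forcefield()

    n1 = len(spec.domain1_sequence)
    nh = len(spec.hinge_sequence)
    seq = spec.domain1_sequence + spec.hinge_sequence + spec.domain2_sequence
    rec_atoms = _chain_atoms(seq, "A", np.zeros(3))
    for r1, r2 in spec.disulfide_pairs:
        _close_disulfide(rec_atoms, "A", r1, r2)

    # rotate domain 2 about the z-axis through the last hinge CA
    d2_first = n1 + nh + 1
    pivot = next(a.xyz.copy() for a in rec_atoms
                 if a.resid == n1 + nh and a.name == "CA")
    rot = _rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                               np.radians(spec.base_angle))
    for a in rec_atoms:
        if a.resid >= d2_first:
            a.xyz = rot @ (a.xyz - pivot) + pivot

    lig_atoms = _chain_atoms(spec.ligand_sequence, "B",
                             np.array(spec.ligand_offset))

    atoms = rec_atoms + lig_atoms
    if spec.jitter > 0:
        noise = rng.normal(0.0, spec.jitter, size=(len(atoms), 3))
        for a, dn in zip(atoms, noise):
            a.xyz = a.xyz + dn

    structure = Structure(atoms, title="toy receptor-ligand complex")
    structure, topology = assign_parameters(structure, params)

    last_resid = n1 + nh + len(spec.domain2_sequence)
    anchors = AnchorPair(v1=(("A", 2, "CA"), ("A", n1 - 1, "CA")),
                         v2=(("A", d2_first, "CA"), ("A", last_resid, "CA")))
    receptor_indices = [i for i, a in enumerate(structure.atoms) if a.chain == "A"]
    ligand_indices = [i for i, a in enumerate(structure.atoms) if a.chain == "B"]
    pivot_index = next(i for i, a in enumerate(structure.atoms)
                       if a.chain == "A" and a.resid == n1 + nh and a.name == "CA")
    return ToyComplex(structure=structure, topology=topology, params=params,
                      anchors=anchors, receptor_indices=receptor_indices,
                      ligand_indices=ligand_indices,
                      domain2_first_resid=d2_first, pivot_index=pivot_index)


# ---------------------------------------------------------------------------
# Hinge trajectories
# ---------------------------------------------------------------------------

@dataclass
class HingeTrajectorySpec:
    mean_angle: float = 110.0      # deg
    sd: float = 5.0                # deg
    n_frames: int = 100
    thermal_noise_rms: float = 0.0  # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def make_hinge_trajectory(toy: ToyComplex, spec: HingeTrajectorySpec
                          ) -> tuple[Trajectory, np.ndarray]:
    """Rigidly rotate domain 2 about the hinge so the anchor angle follows
    N(mean, sd) per frame; returns the trajectory and the ground-truth
    per-frame target angles."""
    rng = np.random.default_rng(spec.seed)
    coords0 = toy.structure.coords
    idx = toy.anchors.resolve(toy.structure)
    v1 = coords0[idx[1]] - coords0[idx[0]]
    v2 = coords0[idx[3]] - coords0[idx[2]]
    theta0 = np.degrees(np.arccos(np.clip(
        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
    axis = np.cross(v1, v2)
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("anchor vectors are parallel; hinge axis undefined")
    pivot = coords0[toy.pivot_index]
    d2_mask = np.array([a.chain == "A" and a.resid >= toy.domain2_first_resid
                        for a in toy.structure.atoms])

    targets = (np.full(spec.n_frames, spec.mean_angle) if spec.sd == 0
               else rng.normal(spec.mean_angle, spec.sd, spec.n_frames))
    targets = np.clip(targets, 1.0, 179.0)
    frames = []
    for t in targets:
        delta = np.radians(t - theta0)
        rot = _rotation_about_axis(axis, delta)
        frame = coords0.copy()
        frame[d2_mask] = (coords0[d2_mask] - pivot) @ rot.T + pivot
        if spec.thermal_noise_rms > 0:
            frame = frame + rng.normal(0.0, spec.thermal_noise_rms,
                                       size=frame.shape)
        frames.append(frame)
    return Trajectory(frames), targets


# ---------------------------------------------------------------------------
# Module chains
# ---------------------------------------------------------------------------

@dataclass
class ModuleChainSpec:
    target_curvature: float = 0.25   # 1/A
    n_modules: int = 7
    chord_length: float | None = None  # A between consecutive points; auto if None
    noise_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_curvature < 0:
            raise ValueError("curvature must be non-negative")
        if self.n_modules < 3:
            raise ValueError("need at least 3 modules")


def make_module_chain(spec: ModuleChainSpec | None = None) -> np.ndarray:
    """Points on a circular arc of curvature kappa (collinear when kappa=0),
    rotated into a seeded random 3-D orientation, plus optional noise.

    The default chord keeps the arc shallow so a quadratic fit recovers the
    circle's curvature closely.
    """
    if spec is None:
        spec = ModuleChainSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_modules
    kappa = spec.target_curvature
    if kappa == 0.0:
        chord = spec.chord_length if spec.chord_length else 3.8
        pts = np.stack([np.arange(n) * chord, np.zeros(n), np.zeros(n)], axis=1)
    else:
        radius = 1.0 / kappa
        chord = spec.chord_length if spec.chord_length else 0.08 / kappa
        half = chord / (2.0 * radius)
        if half >= 1.0:
            raise ValueError("chord longer than the arc diameter")
        alpha = 2.0 * np.arcsin(half)
        angles = (np.arange(n) - (n - 1) / 2.0) * alpha
        pts = np.stack([radius * np.sin(angles),
                        radius * (1.0 - np.cos(angles)),
                        np.zeros(n)], axis=1)
    # seeded random proper rotation + translation
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.normal(0.0, 10.0, 3)
    pts = pts @ q.T + shift
    if spec.noise_rms > 0:
        pts = pts + rng.normal(0.0, spec.noise_rms, size=pts.shape)
    return pts


# ---------------------------------------------------------------------------
# Born systems
# ---------------------------------------------------------------------------

@dataclass
class BornSystemSpec:
    charge: float = 1.0
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def make_born_system(spec: BornSystemSpec | None = None,
                     eps_in: float = 1.0, eps_out: float = 80.0
                     ) -> tuple[Structure, ParameterSet, float]:
    """Single-ion structure plus parameters and the analytic Born solvation
    energy sidecar: -166.0358 * q^2 / r * (1/eps_in - 1/eps_out)."""
    if spec is None:
        spec = BornSystemSpec()
    params = ParameterSet()
    params.atoms[("ION", "ION")] = ("X", spec.charge, 22.99, spec.radius,
                                    spec.radius, 0.1)
    atom = Atom(name="ION", element="X", resname="ION", resid=1, chain="A",
                xyz=np.zeros(3))
    structure, _ = assign_parameters(Structure([atom], title="Born ion"), params)
    from flexbind.pb import born_energy
    analytic = born_energy(spec.charge, spec.radius, eps_in, eps_out)
    return structure, params, analytic


# ---------------------------------------------------------------------------
# Binding ensembles
# ---------------------------------------------------------------------------

def make_ensemble(toy: ToyComplex, n_frames: int = 5,
                  fluctuation_rms: float = 0.03, seed: int = 0,
                  ligand_stretch: float = 0.0
                  ) -> dict[str, Trajectory]:
    """Complex / receptor / ligand trajectories.

    Complex frames are the reference plus Gaussian fluctuations; free-species
    frames are generated independently.  ``ligand_stretch`` displaces the
    carbonyl O of the first ligand residue radially along its C-O bond in the
    *free* ligand ensemble, creating a known bonded-strain offset.
    """
    rng = np.random.default_rng(seed)
    coords = toy.structure.coords
    ridx = np.asarray(toy.receptor_indices, dtype=int)
    lidx = np.asarray(toy.ligand_indices, dtype=int)

    def jitter(base, n):
        return [base + rng.normal(0.0, fluctuation_rms, size=base.shape)
                for _ in range(n)]

    complex_frames = jitter(coords, n_frames)
    receptor_frames = jitter(coords[ridx], n_frames)

    lig_base = coords[lidx].copy()
    if ligand_stretch != 0.0:
        lig_atoms = [toy.structure.atoms[i] for i in lidx]
        first_resid = min(a.resid for a in lig_atoms)
        i_c = next(k for k, a in enumerate(lig_atoms)
                   if a.resid == first_resid and a.name == "C")
        i_o = next(k for k, a in enumerate(lig_atoms)
                   if a.resid == first_resid and a.name == "O")
        u = lig_base[i_o] - lig_base[i_c]
        u = u / np.linalg.norm(u)
        lig_base[i_o] = lig_base[i_o] + ligand_stretch * u
    ligand_frames = jitter(lig_base, n_frames)

    return {"complex": Trajectory(complex_frames),
            "receptor": Trajectory(receptor_frames),
            "ligand": Trajectory(ligand_frames)}
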