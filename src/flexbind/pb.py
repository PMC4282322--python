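"""Finite-difference linearized Poisson-Boltzmann solver.

Solves div(eps grad phi) - kappa2 phi = -4 pi k rho on a cubic grid with a
7-point stencil.  Potentials are carried in kcal/mol/e (the Coulomb constant
k = 332.0716 is folded into the source term), charges in e, lengths in
Angstrom.  The dielectric boundary is the van der Waals union of the
pb_radius spheres; edge dielectrics use harmonic-mean smoothing over sample
points along each edge (``n_edge_samples=1`` reduces to a midpoint test).
Dirichlet boundary values are Debye-Hueckel screened Coulomb potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from flexbind.mm import COULOMB_CONSTANT
from flexbind.structure import Structure

__all__ = ["PBOptions", "PBGrid", "PolarSolvation", "build_grid", "solve_lpb",
           "polar_solvation", "grid_resolution_study", "born_energy"]

GAS_CONSTANT = 1.9872e-3       # kcal/mol/K
AVOGADRO_PER_L_TO_A3 = 6.02214076e-4   # (mol/L) -> ions per A^3


@dataclass
class PBOptions:
    spacing: float = 0.5          # A
    eps_in: float = 1.0
    eps_out: float = 80.0
    ionic_strength: float = 0.1   # mol/L
    temperature: float = 300.0    # K
    stern: float = 2.0            # A
    padding: float = 10.0         # A
    tol: float = 1e-6             # relative residual
    max_iter: int = 20000
    max_nodes: int = 8_000_000
    n_edge_samples: int = 9       # dielectric smoothing samples per edge

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.eps_in < 1 or self.eps_out < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.padding < 5:
            raise ValueError("padding must be at least 5 A")

    @property
    def kappa2_bar(self) -> float:
        """Modified screening factor eps_out * kappa_D^2 in 1/A^2.

        kappa_D^2 = 8 pi e^2 I N_A / (1000 eps_out k_B T); the eps_out
        cancels in the product used by the stencil.
        """
        i_num = self.ionic_strength * AVOGADRO_PER_L_TO_A3
        return 8.0 * np.pi * COULOMB_CONSTANT * i_num / (GAS_CONSTANT * self.temperature)

    @property
    def kappa_debye(self) -> float:
        """Inverse Debye length in the solvent, 1/A."""
        return float(np.sqrt(self.kappa2_bar / self.eps_out))


@dataclass
class PBGrid:
    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: float
    eps_edges: tuple[np.ndarray, np.ndarray, np.ndarray]  # x-, y-, z-edge maps
    kappa2: np.ndarray            # node map, modified units (1/A^2)
    charge: np.ndarray            # node charges, e (sums to total charge)
    coords: np.ndarray = field(repr=False, default=None)
    charges: np.ndarray = field(repr=False, default=None)
    radii: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class PolarSolvation:
    g_pb: float                   # kcal/mol
    spacing: float
    shape: tuple[int, int, int]
    iterations: int
    converged: bool


def _inside_union(points: np.ndarray, centers: np.ndarray,
                  radii: np.ndarray) -> np.ndarray:
    """Boolean: point lies inside the union of spheres (dense point list)."""
    inside = np.zeros(points.shape[0], dtype=bool)
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        d2 = ((points - c) ** 2).sum(axis=1)
        inside |= d2 < r * r
    return inside


def _mark_inside(mask: np.ndarray, origin: np.ndarray, h: float,
                 centers: np.ndarray, radii: np.ndarray,
                 offset: np.ndarray) -> None:
    """OR into ``mask`` the grid points (``origin + offset + idx*h``) lying
    inside any sphere, touching only the local subgrid around each sphere."""
    shape = np.array(mask.shape)
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        rel = (c - origin - offset) / h
        lo = np.maximum(np.ceil(rel - r / h).astype(int), 0)
        hi = np.minimum(np.floor(rel + r / h).astype(int), shape - 1)
        if np.any(hi < lo):
            continue
        axes = [np.arange(lo[d], hi[d] + 1) * h + origin[d] + offset[d] - c[d]
                for d in range(3)]
        d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
              + axes[2][None, None, :] ** 2)
        view = mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        view |= d2 < r * r


def _edge_eps(axis: int, shape, origin, h, centers, radii,
              options: PBOptions) -> np.ndarray:
    """Harmonic-mean dielectric along the edges in one axis direction."""
    eshape = list(shape)
    eshape[axis] -= 1
    nsamp = max(1, options.n_edge_samples)
    fracs = (np.arange(nsamp) + 0.5) / nsamp
    inv_eps = np.zeros(eshape)
    offset = np.zeros(3)
    for f in fracs:
        offset[:] = 0.0
        offset[axis] = f * h
        inside = np.zeros(eshape, dtype=bool)
        _mark_inside(inside, np.asarray(origin), h, centers, radii, offset)
        inv_eps += np.where(inside, 1.0 / options.eps_in, 1.0 / options.eps_out)
    return nsamp / inv_eps


def build_grid(structure: Structure, options: PBOptions,
               origin: np.ndarray | None = None,
               shape: tuple[int, int, int] | None = None) -> PBGrid:
    """Cubic-cell grid covering the structure plus padding.

    ``origin``/``shape`` may be supplied to force an identical grid for a
    reference solve.
    """
    coords = structure.coords
    charges = structure.charges
    radii = structure.pb_radii
    h = options.spacing

    if origin is None or shape is None:
        lo = (coords - radii[:, None]).min(axis=0) - options.padding
        hi = (coords + radii[:, None]).max(axis=0) + options.padding
        n = np.ceil((hi - lo) / h).astype(int) + 1
        origin = lo
        shape = tuple(int(x) for x in n)
    if int(np.prod(shape)) > options.max_nodes:
        raise MemoryError(
            f"grid of {np.prod(shape)} nodes exceeds the {options.max_nodes} "
            f"bound; use a coarser spacing than {h} A")

    nx, ny, nz = shape

    eps_edges = tuple(
        _edge_eps(axis, shape, origin, h, coords, radii, options)
        for axis in range(3))

    # ion accessibility: nodes outside all (radius + stern) spheres
    if options.ionic_strength > 0:
        inside_stern = np.zeros(shape, dtype=bool)
        _mark_inside(inside_stern, np.asarray(origin, dtype=float), h,
                     coords, radii + options.stern, np.zeros(3))
        kappa2 = np.where(inside_stern, 0.0, options.kappa2_bar)
    else:
        kappa2 = np.zeros(shape)

    # trilinear charge spreading
    charge = np.zeros(shape)
    rel = (coords - origin) / h
    base = np.floor(rel).astype(int)
    frac = rel - base
    if np.any(base < 0) or np.any(base + 1 >= np.array(shape)):
        raise ValueError("atom charge falls outside the grid")
    for (bx, by, bz), (fx, fy, fz), q in zip(base, frac, charges):
        for dx in (0, 1):
            wx = fx if dx else 1 - fx
            for dy in (0, 1):
                wy = fy if dy else 1 - fy
                for dz in (0, 1):
                    wz = fz if dz else 1 - fz
                    charge[bx + dx, by + dy, bz + dz] += q * wx * wy * wz

    return PBGrid(origin=np.asarray(origin, dtype=float), shape=shape, spacing=h,
                  eps_edges=eps_edges, kappa2=kappa2, charge=charge,
                  coords=coords, charges=charges, radii=radii)


def _boundary_potential(grid: PBGrid, options: PBOptions,
                        eps_solvent: float, kappa_debye: float) -> np.ndarray:
    """Debye-Hueckel screened Coulomb potential of all atoms, full node map
    (only the outermost layer is consumed)."""
    nx, ny, nz = grid.shape
    phi = np.zeros(grid.shape)
    # collect boundary node coordinates
    mask = np.zeros(grid.shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    idx = np.argwhere(mask)
    pts = grid.origin + idx * grid.spacing
    vals = np.zeros(idx.shape[0])
    for c, q, a in zip(grid.coords, grid.charges, grid.radii):
        if q == 0.0:
            continue
        r = np.linalg.norm(pts - c, axis=1)
        r = np.maximum(r, 1e-6)
        if kappa_debye > 0:
            screen = np.exp(-kappa_debye * np.maximum(r - a, 0.0)) / (1.0 + kappa_debye * a)
        else:
            screen = 1.0
        vals += COULOMB_CONSTANT * q * screen / (eps_solvent * r)
    phi[mask] = vals
    return phi


def solve_lpb(grid: PBGrid, options: PBOptions,
              uniform_eps: float | None = None,
              no_salt: bool = False) -> tuple[np.ndarray, int]:
    """Solve the linearized PB equation on the grid; returns (phi, iterations).

    ``uniform_eps`` overrides the dielectric maps with a constant (used for
    the reference solve); ``no_salt`` zeroes the screening term.
    """
    nx, ny, nz = grid.shape
    h = grid.spacing
    if uniform_eps is not None:
        eps_x = np.full((nx - 1, ny, nz), uniform_eps)
        eps_y = np.full((nx, ny - 1, nz), uniform_eps)
        eps_z = np.full((nx, ny, nz - 1), uniform_eps)
        eps_solvent = uniform_eps
    else:
        eps_x, eps_y, eps_z = grid.eps_edges
        eps_solvent = options.eps_out
    kappa2 = np.zeros(grid.shape) if no_salt else grid.kappa2
    kappa_d = 0.0 if (no_salt or options.ionic_strength <= 0) else options.kappa_debye

    phi_b = _boundary_potential(grid, options, eps_solvent, kappa_d)

    interior = np.ones(grid.shape, dtype=bool)
    interior[0, :, :] = interior[-1, :, :] = False
    interior[:, 0, :] = interior[:, -1, :] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    n_int = int(interior.sum())
    lin = -np.ones(grid.shape, dtype=np.int64)
    lin[interior] = np.arange(n_int)

    # assemble  A phi = b  with A = -(sum_d eps (phi_nbr - phi_0)) + kappa2 h^2 phi_0
    # and b = 4 pi k q_node / h + boundary contributions (SPD form)
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    vv: list[np.ndarray] = []
    diag = kappa2[interior] * h * h
    b = 4.0 * np.pi * COULOMB_CONSTANT * grid.charge[interior] / h

    ix, iy, iz = np.where(interior)
    me = lin[ix, iy, iz]

    def couple(eps_map, nix, niy, niz, eix, eiy, eiz):
        nonlocal diag, b
        e = eps_map[eix, eiy, eiz]
        diag = diag + e
        nbr = lin[nix, niy, niz]
        inb = nbr >= 0
        ii.append(me[inb])
        jj.append(nbr[inb])
        vv.append(-e[inb])
        # Dirichlet neighbours move to the RHS
        out = ~inb
        if out.any():
            np.add.at(b, me[out], e[out] * phi_b[nix[out], niy[out], niz[out]])

    couple(eps_x, ix - 1, iy, iz, ix - 1, iy, iz)
    couple(eps_x, ix + 1, iy, iz, ix, iy, iz)
    couple(eps_y, ix, iy - 1, iz, ix, iy - 1, iz)
    couple(eps_y, ix, iy + 1, iz, ix, iy, iz)
    couple(eps_z, ix, iy, iz - 1, ix, iy, iz - 1)
    couple(eps_z, ix, iy, iz + 1, ix, iy, iz)

    rows = np.concatenate(ii + [me])
    cols = np.concatenate(jj + [me])
    vals = np.concatenate(vv + [diag])
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(n_int, n_int))

    m_inv = sparse.diags(1.0 / a.diagonal())
    iterations = 0

    def count(_):
        nonlocal iterations
        iterations += 1

    x, info = cg(a, b, rtol=options.tol, maxiter=options.max_iter, M=m_inv,
                 callback=count)
    if info != 0:
        res = np.linalg.norm(a @ x - b) / max(np.linalg.norm(b), 1e-300)
        raise RuntimeError(
            f"PB solver did not converge in {options.max_iter} iterations "
            f"(relative residual {res:.2e})")

    phi = phi_b.copy()
    phi[interior] = x
    return phi, iterations


def polar_solvation(structure: Structure, options: PBOptions) -> PolarSolvation:
    """Polar solvation free energy: grid charging energy in the solvated
    system minus the same quantity in a uniform eps_in, salt-free reference
    solved on the identical grid (self-energy cancellation)."""
    grid = build_grid(structure, options)
    if not np.any(grid.charges):
        return PolarSolvation(g_pb=0.0, spacing=grid.spacing, shape=grid.shape,
                              iterations=0, converged=True)
    phi_solv, it1 = solve_lpb(grid, options)
    phi_ref, it2 = solve_lpb(grid, options, uniform_eps=options.eps_in,
                             no_salt=True)
    g = 0.5 * float((grid.charge * (phi_solv - phi_ref)).sum())
    return PolarSolvation(g_pb=g, spacing=grid.spacing, shape=grid.shape,
                          iterations=it1 + it2, converged=True)


def grid_resolution_study(structure: Structure, spacings,
                          options: PBOptions | None = None):
    """polar_solvation at each spacing; returns a list of (h, g_pb, diff)."""
    if options is None:
        options = PBOptions()
    rows = []
    prev = None
    for h in spacings:
        res = polar_solvation(structure, replace(options, spacing=h))
        diff = None if prev is None else res.g_pb - prev
        rows.append((h, res.g_pb, diff))
        prev = res.g_pb
    return rows


def born_energy(charge: float, radius: float, eps_in: float = 1.0,
                eps_out: float = 80.0) -> float:
    """Analytic Born solvation energy, kcal/mol."""
    return -0.5 * COULOMB_CONSTANT * charge ** 2 / radius * (1.0 / eps_in - 1.0 / eps_out)
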