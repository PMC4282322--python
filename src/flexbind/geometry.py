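"""Flexibility and shape descriptors.

Rigid-body superposition, interdomain angles from anchor vectors, curvature of
the disulfide-module spine, gyration tensor, pair distribution functions, PCA
and contact persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flexbind.structure import Structure, Trajectory, select

__all__ = [
    "DEFAULT_DOMAIN_MAP",
    "AnchorPair",
    "DisulfideModule",
    "CurveFit",
    "ShapeDescriptors",
    "DistanceHistogram",
    "PCAResult",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "interdomain_angle",
    "angle_series",
    "find_disulfide_modules",
    "fit_quadratic_curve",
    "max_curvature",
    "gyration_descriptors",
    "pair_distribution",
    "pca",
    "mode_overlap",
    "project",
    "contact_fraction",
]

#: Default subdomain boundaries of the receptor ectodomain (mature numbering).
DEFAULT_DOMAIN_MAP: dict[str, tuple[int, int]] = {
    "I": (1, 165),
    "II": (166, 310),
    "III": (311, 480),
    "IV": (481, 614),
}

#: Default anchor atoms defining the two subdomain orientation vectors:
#: V1 runs Val36 -> Glu118 (Subdomain I), V2 runs Ser340 -> Glu431
#: (Subdomain III), both over C-alpha atoms.
DEFAULT_ANCHOR_RESIDS = ((36, 118), (340, 431))


@dataclass(frozen=True)
class AnchorPair:
    """Two anchor vectors, each a ((chain, resid, atomname), (chain, resid, atomname))."""

    v1: tuple[tuple[str, int, str], tuple[str, int, str]]
    v2: tuple[tuple[str, int, str], tuple[str, int, str]]

    @classmethod
    def calpha(cls, chain: str, resids=DEFAULT_ANCHOR_RESIDS) -> "AnchorPair":
        (a1, b1), (a2, b2) = resids
        return cls(v1=((chain, a1, "CA"), (chain, b1, "CA")),
                   v2=((chain, a2, "CA"), (chain, b2, "CA")))

    def resolve(self, structure: Structure) -> np.ndarray:
        """Return the four anchor atom indices as [v1_from, v1_to, v2_from, v2_to]."""
        idx = []
        for chain, resid, name in (*self.v1, *self.v2):
            hits = [i for i, a in enumerate(structure.atoms)
                    if a.chain == chain and a.resid == resid and a.name == name]
            if not hits:
                raise ValueError(f"anchor atom {chain}/{resid}/{name} not found")
            idx.append(hits[0])
        return np.array(idx, dtype=int)


@dataclass
class DisulfideModule:
    cys_pair: tuple[int, int]
    member_resids: tuple[int, int]  # inclusive span
    com: np.ndarray


@dataclass
class CurveFit:
    """Quadratic fit v = a*u**2 + b*u + c in the least-squares plane of the data."""

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    a: float
    b: float
    c: float
    u_range: tuple[float, float]
    residual: float


@dataclass
class ShapeDescriptors:
    gyration_eigenvalues: np.ndarray  # descending, Angstrom^2
    rg: float
    dmax: float


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    weights: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PCAResult:
    mean: np.ndarray            # (n_sel, 3)
    modes: np.ndarray           # (n_modes, 3*n_sel), orthonormal rows
    variances: np.ndarray       # descending, Angstrom^2
    projections: np.ndarray     # (n_frames, n_modes)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch), proper rotation enforced.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mc = (wn[:, None] * mobile).sum(axis=0)
    rc = (wn[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    # collinearity check: rank of the weighted point cloud
    if np.linalg.matrix_rank(m0 * np.sqrt(wn)[:, None], tol=1e-8) < 2:
        raise ValueError("all points are collinear; superposition is degenerate")
    h = (wn[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt((wn * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsd_series(trajectory: Trajectory, reference: np.ndarray,
                fit_indices, measure_indices) -> np.ndarray:
    """Per frame: superpose on ``fit_indices``, report RMSD over ``measure_indices``."""
    fit_indices = np.asarray(list(fit_indices), dtype=int)
    measure_indices = np.asarray(list(measure_indices), dtype=int)
    if fit_indices.size == 0 or measure_indices.size == 0:
        raise ValueError("fit and measure selections must be nonempty")
    reference = np.asarray(reference, dtype=float)
    out = np.empty(len(trajectory))
    for f, frame in enumerate(trajectory.frames):
        rot, trans, _ = superpose(frame[fit_indices], reference[fit_indices])
        fitted = apply_transform(frame[measure_indices], rot, trans)
        out[f] = _rmsd(fitted, reference[measure_indices])
    return out


# ---------------------------------------------------------------------------
# Interdomain angle
# ---------------------------------------------------------------------------

def _angle_from_coords(coords: np.ndarray, idx: np.ndarray) -> float:
    v1 = coords[idx[1]] - coords[idx[0]]
    v2 = coords[idx[3]] - coords[idx[2]]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("zero-length anchor vector")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def interdomain_angle(structure: Structure, anchors: AnchorPair) -> float:
    """Angle (degrees, in [0, 180]) between the two anchor vectors."""
    idx = anchors.resolve(structure)
    return _angle_from_coords(structure.coords, idx)


def angle_series(trajectory: Trajectory, structure: Structure,
                 anchors: AnchorPair, bin_width: float = 1.0
                 ) -> tuple[np.ndarray, DistanceHistogram]:
    """Per-frame anchor angle plus its histogram (default 1 degree bins)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    idx = anchors.resolve(structure)
    angles = np.array([_angle_from_coords(frame, idx) for frame in trajectory.frames])
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, edges = np.histogram(angles, bins=edges)
    return angles, DistanceHistogram(bin_edges=edges, weights=counts.astype(float))


# ---------------------------------------------------------------------------
# Disulfide modules and spine curvature
# ---------------------------------------------------------------------------

def find_disulfide_modules(structure: Structure, domain_range: tuple[int, int],
                           sg_cutoff: float = 2.5) -> list[DisulfideModule]:
    """Disulfide-bridged residue spans within ``domain_range``, ordered along
    the sequence; COM is mass-weighted over all atoms of the member residues.

    Atoms with zero mass (crystal structures carry no parameters) fall back to
    unit weights.
    """
    lo, hi = domain_range
    sg = [(i, a) for i, a in enumerate(structure.atoms)
          if a.name == "SG" and lo <= a.resid <= hi]
    coords = structure.coords
    partner: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for x in range(len(sg)):
        for y in range(x + 1, len(sg)):
            i, ai = sg[x]
            j, aj = sg[y]
            if ai.resid == aj.resid and ai.chain == aj.chain:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= sg_cutoff:
                for k in (i, j):
                    if k in partner:
                        a = structure.atoms[k]
                        raise ValueError(
                            f"cysteine {a.chain}/{a.resid} bridges two partners")
                partner[i] = j
                partner[j] = i
                pairs.append((i, j))

    modules: list[DisulfideModule] = []
    for i, j in pairs:
        r1, r2 = sorted((structure.atoms[i].resid, structure.atoms[j].resid))
        chain = structure.atoms[i].chain
        member = [k for k, a in enumerate(structure.atoms)
                  if a.chain == chain and r1 <= a.resid <= r2]
        w = np.array([structure.atoms[k].mass for k in member])
        if w.sum() <= 0:
            w = np.ones(len(member))
        com = (w[:, None] * coords[member]).sum(axis=0) / w.sum()
        modules.append(DisulfideModule(cys_pair=(r1, r2),
                                       member_resids=(r1, r2), com=com))
    modules.sort(key=lambda m: m.cys_pair[0])
    return modules


def fit_quadratic_curve(points: np.ndarray) -> CurveFit:
    """Fit v = a*u**2 + b*u + c in the least-squares plane of the points.

    The plane is spanned by the two leading principal axes of the point cloud;
    u runs along the direction of largest spread.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a quadratic fit")
    origin = pts.mean(axis=0)
    centered = pts - origin
    if np.max(np.linalg.norm(centered, axis=1)) < 1e-9:
        raise ValueError("points are coincident")
    # principal axes of the cloud; eigenvalues ascending from eigh
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    u_axis = evecs[:, 2]
    v_axis = evecs[:, 1]
    u = centered @ u_axis
    v = centered @ v_axis
    design = np.stack([u ** 2, u, np.ones_like(u)], axis=1)
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    a, b, c = (float(x) for x in coef)
    # snap numerically-zero curvature (collinear input in a rotated frame)
    span = float(u.max() - u.min())
    if abs(a) * span ** 2 < 1e-9 * max(span, 1.0):
        a = 0.0
    residual = float(np.sqrt(np.mean((design @ coef - v) ** 2)))
    return CurveFit(origin=origin, u_axis=u_axis, v_axis=v_axis, a=a, b=b, c=c,
                    u_range=(float(u.min()), float(u.max())), residual=residual)


def max_curvature(fit: CurveFit) -> float:
    """Maximum of kappa(u) = |2a| / (1 + (2au + b)^2)^{3/2} over the data's
    u-range.  Equals 2|a| when the parabola's vertex lies inside the range."""
    a, b = fit.a, fit.b
    if a == 0.0:
        return 0.0
    u_lo, u_hi = fit.u_range
    u_vertex = -b / (2.0 * a)
    candidates = [u_lo, u_hi]
    if u_lo <= u_vertex <= u_hi:
        candidates.append(u_vertex)
    kappa = [abs(2 * a) / (1 + (2 * a * u + b) ** 2) ** 1.5 for u in candidates]
    return float(max(kappa))


# ---------------------------------------------------------------------------
# Gyration tensor, P(r)
# ---------------------------------------------------------------------------

def gyration_descriptors(coords: np.ndarray, masses: np.ndarray | None = None,
                         mass_weighted: bool = True) -> ShapeDescriptors:
    """Gyration-tensor eigenvalues (descending), Rg and Dmax of a point set."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("empty selection")
    n = coords.shape[0]
    if mass_weighted and masses is not None and np.sum(masses) > 0:
        w = np.asarray(masses, dtype=float)
    else:
        w = np.ones(n)
    w = w / w.sum()
    center = (w[:, None] * coords).sum(axis=0)
    d = coords - center
    tensor = (w[:, None] * d).T @ d
    evals = np.linalg.eigvalsh(tensor)[::-1]
    evals = np.clip(evals, 0.0, None)
    rg = float(np.sqrt(evals.sum()))
    if n == 1:
        dmax = 0.0
    else:
        from scipy.spatial.distance import pdist
        dmax = float(pdist(coords).max())
    return ShapeDescriptors(gyration_eigenvalues=evals, rg=rg, dmax=dmax)


def pair_distribution(frames, bin_width: float = 1.0,
                      normalize: bool = False) -> DistanceHistogram:
    """Histogram of all pairwise distances, averaged over frames.

    ``frames`` is a single (n, 3) array or a sequence of them.  In raw mode the
    total weight per frame is n*(n-1)/2; ``normalize=True`` rescales to unit
    area.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] < 2:
        raise ValueError("need at least 2 atoms for a pair distribution")
    from scipy.spatial.distance import pdist
    dists = [pdist(f) for f in frames]
    dmax = max(d.max() for d in dists)
    n_bins = int(np.floor(dmax / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)[: n_bins + 1]
    acc = np.zeros(n_bins)
    for d in dists:
        counts, _ = np.histogram(d, bins=edges)
        acc += counts
    acc /= len(frames)
    if normalize:
        total = acc.sum() * bin_width
        if total > 0:
            acc = acc / total
    return DistanceHistogram(bin_edges=edges, weights=acc)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(trajectory: Trajectory, indices, n_modes: int | None = None,
        n_iter: int = 3) -> PCAResult:
    """Cartesian PCA over a selection, frames superposed onto the trajectory
    mean (fit on the same selection, iterated to self-consistency)."""
    indices = np.asarray(list(indices), dtype=int)
    if indices.size == 0:
        raise ValueError("empty selection")
    n_frames = len(trajectory)
    if n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if n_modes is None:
        n_modes = min(3 * indices.size, n_frames - 1)
    if n_modes > 3 * indices.size or n_modes > n_frames:
        raise ValueError("fewer frames than requested modes")

    sub = np.stack([f[indices] for f in trajectory.frames])  # (F, n, 3)
    ref = sub[0]
    for _ in range(n_iter):
        fitted = np.empty_like(sub)
        for f in range(n_frames):
            rot, trans, _ = superpose(sub[f], ref)
            fitted[f] = apply_transform(sub[f], rot, trans)
        new_ref = fitted.mean(axis=0)
        if np.allclose(new_ref, ref, atol=1e-10):
            ref = new_ref
            break
        ref = new_ref
    sub = fitted

    flat = sub.reshape(n_frames, -1)
    mean = flat.mean(axis=0)
    x = flat - mean
    cov = x.T @ x / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_modes]
    variances = np.clip(evals[order], 0.0, None)
    modes = evecs[:, order].T
    projections = x @ modes.T
    return PCAResult(mean=mean.reshape(-1, 3), modes=modes,
                     variances=variances, projections=projections)


def mode_overlap(modes_a: np.ndarray, modes_b: np.ndarray, k: int) -> np.ndarray:
    """k x k matrix of absolute scalar products between two mode sets."""
    a = np.asarray(modes_a)[:k]
    b = np.asarray(modes_b)[:k]
    return np.abs(a @ b.T)


def project(trajectory: Trajectory, indices, result: PCAResult,
            k: int) -> np.ndarray:
    """Project frames onto the first k modes of a PCAResult (Angstrom)."""
    indices = np.asarray(list(indices), dtype=int)
    out = np.empty((len(trajectory), k))
    ref = result.mean
    for f, frame in enumerate(trajectory.frames):
        rot, trans, _ = superpose(frame[indices], ref)
        fitted = apply_transform(frame[indices], rot, trans)
        out[f] = result.modes[:k] @ (fitted.reshape(-1) - ref.reshape(-1))
    return out


# ---------------------------------------------------------------------------
# Contact persistence
# ---------------------------------------------------------------------------

def contact_fraction(trajectory: Trajectory, atom_a: int, atom_b: int,
                     cutoff: float) -> float:
    """Fraction of frames in which two atoms are closer than ``cutoff``."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    d = np.array([np.linalg.norm(f[atom_a] - f[atom_b]) for f in trajectory.frames])
    return float(np.mean(d < cutoff))


def structure_selection_coords(structure: Structure, expression: str) -> np.ndarray:
    idx = select(structure, expression)
    if not idx:
        raise ValueError(f"selection {expression!r} matched no atoms")
    return structure.coords[idx]
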