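"""Rotational/translational entropies and reduced-region normal-mode
vibrational entropy.

Normal modes are computed for a flexible region only: buffer atoms are held
fixed during minimization, contribute to the potential, but carry no Hessian
rows.  The Hessian is a central finite difference of the analytic MM
gradient, mass-weighted and symmetrized before diagonalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from flexbind.mm import energy_and_gradient, total_energy, total_gradient
from flexbind.structure import Structure, Topology

__all__ = [
    "GAS_CONSTANT",
    "RegionPartition",
    "ModeSpectrum",
    "EntropyResult",
    "BindingEntropy",
    "classical_rt_energy",
    "translational_entropy",
    "rotational_entropy",
    "reduced_region",
    "minimize",
    "normal_modes",
    "vibrational_entropy",
]

GAS_CONSTANT = 1.9872e-3          # kcal/mol/K
PLANCK = 6.62607015e-34           # J s
BOLTZMANN = 1.380649e-23          # J/K
AVOGADRO = 6.02214076e23
AMU = 1.66053906660e-27           # kg
C_CM = 2.99792458e10              # cm/s
HC_OVER_KB = PLANCK * C_CM / BOLTZMANN   # cm*K, ~1.4388

# (kcal/mol/A^2/amu) -> s^-2
_LAMBDA_TO_SI = 4184.0 / (AVOGADRO * 1e-20 * AMU)


@dataclass
class RegionPartition:
    flexible: list[int]
    buffer: list[int]
    cutoff: float
    buffer_width: float


@dataclass
class ModeSpectrum:
    frequencies: np.ndarray          # cm^-1, ascending, >= 0
    n_zero: int                      # |lambda| below threshold, skipped
    imaginary: np.ndarray            # cm^-1 magnitudes of negative eigenvalues

    def validate(self) -> None:
        if self.imaginary.size:
            raise ValueError(
                f"{self.imaginary.size} imaginary modes present: "
                f"{np.round(self.imaginary, 2)} cm^-1")


@dataclass
class EntropyResult:
    s_trans: float                   # kcal/mol/K
    s_rot: float
    s_vib: float
    temperature: float

    @property
    def s_rt(self) -> float:
        return self.s_trans + self.s_rot

    def minus_t_s(self, which: str) -> float:
        return -self.temperature * getattr(self, which)


@dataclass
class BindingEntropy:
    """Entropy *differences* of binding, kcal/mol/K, at one temperature."""

    ds_rt: float
    ds_vib: float
    temperature: float


def classical_rt_energy(temperature: float) -> float:
    """Classical energy of the six rotational+translational degrees of
    freedom: 3RT (1.79 kcal/mol at 300 K)."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return 3.0 * GAS_CONSTANT * temperature


def translational_entropy(total_mass: float, temperature: float,
                          standard_concentration: float = 1.0) -> float:
    """Sackur-Tetrode translational entropy, kcal/mol/K.

    ``total_mass`` in amu; ``standard_concentration`` in mol/L (default the
    1 M solution standard state).
    """
    if total_mass <= 0:
        raise ValueError("mass must be positive")
    m = total_mass * AMU
    t = temperature
    volume = 1.0 / (standard_concentration * 1000.0 * AVOGADRO)   # m^3/molecule
    lam = PLANCK / np.sqrt(2.0 * np.pi * m * BOLTZMANN * t)       # thermal wavelength
    s = GAS_CONSTANT * (np.log(volume / lam ** 3) + 2.5)
    return float(s)


def rotational_entropy(coords: np.ndarray, masses: np.ndarray,
                       temperature: float, symmetry_number: float = 1.0) -> float:
    """Classical rigid-rotor entropy from principal moments of inertia,
    kcal/mol/K.  Linear (collinear) structures are rejected."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("rotational entropy needs at least 3 atoms")
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    d = coords - com
    # inertia tensor in amu A^2
    tens = np.zeros((3, 3))
    for w, v in zip(masses, d):
        tens += w * ((v @ v) * np.eye(3) - np.outer(v, v))
    moments = np.linalg.eigvalsh(tens)
    if moments[0] < 1e-8 * max(moments[2], 1.0):
        raise ValueError("linear/collinear structure: rigid-rotor branch "
                         "for nonlinear tops only")
    mom_si = moments * AMU * 1e-20   # kg m^2
    pref = 8.0 * np.pi ** 2 * BOLTZMANN * temperature / PLANCK ** 2
    q_rot = (np.sqrt(np.pi) / symmetry_number) * pref ** 1.5 * np.sqrt(np.prod(mom_si))
    return float(GAS_CONSTANT * (np.log(q_rot) + 1.5))


# ---------------------------------------------------------------------------
# Reduced region
# ---------------------------------------------------------------------------

def reduced_region(structure: Structure, ligand_indices,
                   cutoff: float = 8.0, buffer_width: float = 4.0
                   ) -> RegionPartition:
    """Flexible region = ligand + whole receptor residues with any atom within
    ``cutoff`` of any ligand atom; buffer = whole residues within
    ``cutoff + buffer_width`` of the flexible set; remainder discarded."""
    ligand_indices = list(ligand_indices)
    if not ligand_indices:
        raise ValueError("ligand selection is empty")
    coords = structure.coords
    lig = coords[ligand_indices]
    lig_set = set(ligand_indices)

    residues = structure.residues()

    def residue_min_dist(idxs, ref_points):
        d = np.linalg.norm(coords[idxs][:, None, :] - ref_points[None, :, :], axis=-1)
        return d.min()

    flexible: list[int] = list(ligand_indices)
    flexible_res: list[list[int]] = []
    for chain, resid, icode, idxs in residues:
        if any(i in lig_set for i in idxs):
            continue
        if residue_min_dist(idxs, lig) <= cutoff:
            flexible.extend(idxs)
            flexible_res.append(idxs)
    flex_points = coords[flexible]
    flex_set = set(flexible)

    buffer: list[int] = []
    for chain, resid, icode, idxs in residues:
        if any(i in flex_set for i in idxs):
            continue
        if residue_min_dist(idxs, flex_points) <= cutoff + buffer_width:
            buffer.extend(idxs)
    return RegionPartition(flexible=sorted(flexible), buffer=sorted(buffer),
                           cutoff=cutoff, buffer_width=buffer_width)


# ---------------------------------------------------------------------------
# Minimization and normal modes
# ---------------------------------------------------------------------------

def _rms_gradient(grad: np.ndarray, movable: np.ndarray) -> float:
    return float(np.sqrt((grad[movable] ** 2).mean()))


def minimize(structure: Structure, topology: Topology, movable,
             tolerance: float = 1e-4, max_steps: int = 20000) -> Structure:
    """Gradient-based minimization moving only ``movable`` atoms until the RMS
    gradient over them drops to ``tolerance`` (kcal/mol/A)."""
    movable = np.asarray(sorted(set(movable)), dtype=int)
    if movable.size == 0:
        raise ValueError("movable set is empty")
    coords0 = structure.coords

    def unpack(x):
        c = coords0.copy()
        c[movable] = x.reshape(-1, 3)
        return c

    def fun(x):
        e, g = energy_and_gradient(structure, topology, unpack(x))
        return e, g[movable].reshape(-1)

    x0 = coords0[movable].reshape(-1)
    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                          options={"maxiter": max_steps, "ftol": 1e-13,
                                   "gtol": tolerance * 0.3, "maxcor": 30})
    coords = unpack(res.x)
    rms = _rms_gradient(total_gradient(structure, topology, coords), movable)
    if rms > tolerance:
        # polish with a short steepest-descent/backtracking phase
        c = coords
        e = total_energy(structure, topology, c).e_mm
        step = 1e-3
        for _ in range(2000):
            g = total_gradient(structure, topology, c)
            rms = _rms_gradient(g, movable)
            if rms <= tolerance:
                break
            trial = c.copy()
            trial[movable] = c[movable] - step * g[movable]
            et = total_energy(structure, topology, trial).e_mm
            if et < e:
                c, e = trial, et
                step *= 1.2
            else:
                step *= 0.5
                if step < 1e-12:
                    break
        coords = c
        rms = _rms_gradient(total_gradient(structure, topology, coords), movable)
    if rms > tolerance:
        raise RuntimeError(f"minimization did not converge: RMS gradient "
                           f"{rms:.3e} > {tolerance:.3e} kcal/mol/A")
    out = structure.copy()
    out.coords = coords
    return out


def normal_modes(structure: Structure, topology: Topology, flexible,
                 fd_step: float = 1e-4, zero_threshold: float = 1e-6
                 ) -> ModeSpectrum:
    """Mass-weighted normal modes of the flexible atoms.

    The Hessian is built by central finite differences of the analytic
    gradient (step ``fd_step`` A) over flexible coordinates only; fixed atoms
    still shape the potential.  Eigenvalues below ``-zero_threshold``
    (kcal/mol/A^2/amu) are reported as imaginary modes.
    """
    flexible = np.asarray(sorted(set(flexible)), dtype=int)
    if flexible.size == 0:
        raise ValueError("flexible set is empty")
    coords = structure.coords
    n = flexible.size
    hess = np.zeros((3 * n, 3 * n))
    for a, atom in enumerate(flexible):
        for d in range(3):
            cp = coords.copy()
            cp[atom, d] += fd_step
            gp = total_gradient(structure, topology, cp)[flexible].reshape(-1)
            cm = coords.copy()
            cm[atom, d] -= fd_step
            gm = total_gradient(structure, topology, cm)[flexible].reshape(-1)
            hess[3 * a + d] = (gp - gm) / (2.0 * fd_step)
    hess = 0.5 * (hess + hess.T)

    masses = structure.masses[flexible]
    if np.any(masses <= 0):
        raise ValueError("flexible atoms must have positive masses")
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    hess_mw = hess * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    evals = np.linalg.eigvalsh(hess_mw)

    imag = evals[evals < -zero_threshold]
    zero = (np.abs(evals) <= zero_threshold) | ((evals < 0) & (evals >= -zero_threshold))
    pos = evals[(evals > zero_threshold)]

    def to_cm(lam):
        omega = np.sqrt(np.abs(lam) * _LAMBDA_TO_SI)
        return omega / (2.0 * np.pi * C_CM)

    return ModeSpectrum(frequencies=np.sort(to_cm(pos)),
                        n_zero=int(zero.sum()),
                        imaginary=to_cm(-imag) if imag.size else np.array([]))


def vibrational_entropy(spectrum: ModeSpectrum, temperature: float,
                        classical: bool = False) -> float:
    """Harmonic-oscillator vibrational entropy, kcal/mol/K.

    Quantum by default: S = R * sum[x / (e^x - 1) - ln(1 - e^-x)] with
    x = h nu / kB T.  Zero-frequency modes are skipped with a warning.
    """
    if spectrum.n_zero:
        warnings.warn(f"skipping {spectrum.n_zero} zero-frequency modes",
                      stacklevel=2)
    nu = np.asarray(spectrum.frequencies, dtype=float)
    nu = nu[nu > 0]
    if nu.size == 0:
        return 0.0
    x = HC_OVER_KB * nu / temperature
    if classical:
        s = 1.0 - np.log(x)
    else:
        with np.errstate(over="ignore"):   # x/expm1(x) -> 0 for frozen modes
            s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(GAS_CONSTANT * s.sum())
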