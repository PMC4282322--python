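"""Per-snapshot free energies, binding estimates, reorganization energies,
autocorrelation-aware standard errors and alanine scanning.

The binding free energy is assembled as
``dG = G(complex) - G(receptor) - G(ligand)`` with per-species
``G_noS = E_MM + G_PB + G_SA`` averaged over snapshots.  Two estimators are
provided: *single* (receptor and ligand coordinates extracted from each
complex frame; bonded terms cancel exactly) and *three* (independent
ensembles per species).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from flexbind import mm
from flexbind.pb import PBOptions, polar_solvation
from flexbind.structure import (Structure, Topology, Trajectory,
                                assign_parameters, exclusions_from_bonds)

__all__ = [
    "FreeEnergyOptions",
    "SnapshotEnergies",
    "BindingEstimate",
    "ReorganizationResult",
    "AlanineScanRow",
    "SpeciesEnsemble",
    "snapshot_free_energy",
    "binding_estimate_single",
    "binding_estimate_three",
    "reorganization_energy",
    "standard_error",
    "mutate_to_alanine",
    "alanine_scan",
    "assemble_total",
    "subset_topology",
]

COMPONENTS = ("e_ele", "e_vdw", "e_int", "e_mm", "g_pb", "g_sa", "g_nos")


@dataclass
class FreeEnergyOptions:
    """Knobs shared by all free-energy assembly operations."""

    pb: PBOptions | None = None          # None disables the polar term
    nonpolar: mm.NonpolarParams = field(default_factory=mm.NonpolarParams)
    sasa_probe: float = 1.4
    sasa_points: int = 960
    temperature: float = 300.0
    include_rt_energy: bool = False      # add 3RT per species (cancels in ddG)
    discard: int = 0                     # frames omitted from the head of each trajectory


@dataclass
class SnapshotEnergies:
    species: str
    frame: int
    components: mm.EnergyComponents
    g_pb: float
    g_sa: float
    area: float

    @property
    def g_nos(self) -> float:
        return self.components.e_mm + self.g_pb + self.g_sa

    def as_dict(self) -> dict[str, float]:
        c = self.components
        return {"e_ele": c.e_ele, "e_vdw": c.e_vdw, "e_int": c.e_int,
                "e_mm": c.e_mm, "g_pb": self.g_pb, "g_sa": self.g_sa,
                "g_nos": self.g_nos}


@dataclass
class BindingEstimate:
    mode: str                                      # "single" | "three"
    means: dict[str, float]
    std_errors: dict[str, float | None]
    n_frames: int
    discard: int
    minus_t_ds_rt: float | None = None
    minus_t_ds_v: float | None = None
    temperature: float | None = None

    @property
    def dg_nos(self) -> float:
        return self.means["g_nos"]

    @property
    def minus_t_ds_tot(self) -> float | None:
        if self.minus_t_ds_rt is None or self.minus_t_ds_v is None:
            return None
        return self.minus_t_ds_rt + self.minus_t_ds_v

    @property
    def dg_tot(self) -> float | None:
        t = self.minus_t_ds_tot
        return None if t is None else self.dg_nos + t


@dataclass
class ReorganizationResult:
    species: str
    mean_in_complex: float
    mean_free: float
    se_in_complex: float | None
    se_free: float | None

    @property
    def delta(self) -> float:
        return self.mean_in_complex - self.mean_free


@dataclass
class AlanineScanRow:
    label: str
    chain: str
    resid: int
    means: dict[str, float]
    ddg_nos: float


@dataclass
class SpeciesEnsemble:
    """A parameterized species plus its conformational ensemble."""

    structure: Structure
    topology: Topology
    trajectory: Trajectory


# ---------------------------------------------------------------------------
# Snapshot free energy
# ---------------------------------------------------------------------------

def snapshot_free_energy(structure: Structure, topology: Topology,
                         options: FreeEnergyOptions,
                         coords: np.ndarray | None = None,
                         species: str = "species", frame: int = 0
                         ) -> SnapshotEnergies:
    """G_noS = E_MM + G_PB + G_SA for one conformation of one species."""
    if coords is None:
        coords = structure.coords
    comp = mm.total_energy(structure, topology, coords)
    sasa = mm.surface_area(coords, structure.pb_radii,
                           probe=options.sasa_probe, n_points=options.sasa_points)
    g_sa = mm.nonpolar_solvation(sasa.total, options.nonpolar)
    if options.pb is not None:
        work = structure.copy()
        work.coords = coords
        g_pb = polar_solvation(work, options.pb).g_pb
    else:
        g_pb = 0.0
    return SnapshotEnergies(species=species, frame=frame, components=comp,
                            g_pb=g_pb, g_sa=g_sa, area=sasa.total)


def subset_topology(topology: Topology, indices) -> Topology:
    """Restrict a topology to a subset of atoms, remapping indices and
    rebuilding exclusions from the restricted bond graph."""
    indices = list(indices)
    remap = {old: new for new, old in enumerate(indices)}
    keep = set(indices)

    def inside(*atoms):
        return all(a in keep for a in atoms)

    bonds = [(remap[i], remap[j], k, b0) for i, j, k, b0 in topology.bonds
             if inside(i, j)]
    angles = [(remap[i], remap[j], remap[k], ka, t0)
              for i, j, k, ka, t0 in topology.angles if inside(i, j, k)]
    dihedrals = [(remap[i], remap[j], remap[k], remap[l], kd, n, d)
                 for i, j, k, l, kd, n, d in topology.dihedrals
                 if inside(i, j, k, l)]
    impropers = [(remap[i], remap[j], remap[k], remap[l], kp, p0)
                 for i, j, k, l, kp, p0 in topology.impropers
                 if inside(i, j, k, l)]
    excluded, pairs14 = exclusions_from_bonds(
        len(indices), [(i, j) for i, j, *_ in bonds])
    return Topology(n_atoms=len(indices), bonds=bonds, angles=angles,
                    dihedrals=dihedrals, impropers=impropers,
                    excluded=excluded, pairs14=pairs14, params=topology.params)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def standard_error(series: np.ndarray, frame_interval: float = 1.0
                   ) -> tuple[float, float]:
    """Standard error of the mean of a correlated series.

    Uses the statistical inefficiency g = 1 + 2 * sum of the normalized
    autocorrelation function (summed until it first drops to zero);
    se = sigma * sqrt(g / N).  Returns ``(se, correlation_time)`` with the
    correlation time ``(g - 1) / 2`` expressed in ``frame_interval`` units.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("series too short for a standard error")
    mean = x.mean()
    var = x.var(ddof=0)
    if var == 0.0:
        return 0.0, 0.0
    d = x - mean
    # FFT autocovariance
    nf = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(d, nf)
    acov = np.fft.irfft(f * np.conj(f), nf)[:n].real / n
    rho = acov / acov[0]
    g = 1.0
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        g += 2.0 * (1.0 - k / n) * rho[k]
    g = max(g, 1.0)
    se = float(np.sqrt(var * g / n))
    tau = float((g - 1.0) / 2.0 * frame_interval)
    return se, tau


def _se_or_none(series: np.ndarray) -> float | None:
    if series.size < 2:
        return None
    return standard_error(series)[0]


# ---------------------------------------------------------------------------
# Binding estimates
# ---------------------------------------------------------------------------

def _species_series(structure: Structure, topology: Topology,
                    frames, options: FreeEnergyOptions,
                    species: str) -> dict[str, np.ndarray]:
    rows = [snapshot_free_energy(structure, topology, options, coords=f,
                                 species=species, frame=i).as_dict()
            for i, f in enumerate(frames)]
    out = {k: np.array([r[k] for r in rows]) for k in COMPONENTS}
    if options.include_rt_energy:
        from flexbind.entropy import classical_rt_energy
        rt = classical_rt_energy(options.temperature)
        out["e_mm"] = out["e_mm"] + rt
        out["g_nos"] = out["g_nos"] + rt
    return out


def binding_estimate_single(complex_ensemble: SpeciesEnsemble,
                            receptor_indices, ligand_indices,
                            options: FreeEnergyOptions) -> BindingEstimate:
    """Single-trajectory estimator: receptor/ligand coordinates extracted
    from each complex frame; Delta E_int is identically zero."""
    receptor_indices = list(receptor_indices)
    ligand_indices = list(ligand_indices)
    n_total = len(complex_ensemble.structure)
    if set(receptor_indices) & set(ligand_indices):
        raise ValueError("receptor and ligand selections overlap")
    if sorted(receptor_indices + ligand_indices) != list(range(n_total)):
        raise ValueError("selections must partition the complex")

    frames = complex_ensemble.trajectory.frames[options.discard:]
    if not frames:
        raise ValueError("no frames left after discard")

    rec_struct = complex_ensemble.structure.subset(receptor_indices)
    lig_struct = complex_ensemble.structure.subset(ligand_indices)
    rec_topo = subset_topology(complex_ensemble.topology, receptor_indices)
    lig_topo = subset_topology(complex_ensemble.topology, ligand_indices)
    ridx = np.asarray(receptor_indices, dtype=int)
    lidx = np.asarray(ligand_indices, dtype=int)

    s_cpx = _species_series(complex_ensemble.structure, complex_ensemble.topology,
                            frames, options, "complex")
    s_rec = _species_series(rec_struct, rec_topo, [f[ridx] for f in frames],
                            options, "receptor")
    s_lig = _species_series(lig_struct, lig_topo, [f[lidx] for f in frames],
                            options, "ligand")

    deltas = {k: s_cpx[k] - s_rec[k] - s_lig[k] for k in COMPONENTS}
    # bonded terms cancel exactly in the extraction scheme
    deltas["e_int"] = np.zeros_like(deltas["e_int"])
    deltas["e_mm"] = deltas["e_ele"] + deltas["e_vdw"] + deltas["e_int"]
    deltas["g_nos"] = deltas["e_mm"] + deltas["g_pb"] + deltas["g_sa"]

    means = {k: float(v.mean()) for k, v in deltas.items()}
    ses = {k: _se_or_none(v) for k, v in deltas.items()}
    return BindingEstimate(mode="single", means=means, std_errors=ses,
                           n_frames=len(frames), discard=options.discard,
                           temperature=options.temperature)


def binding_estimate_three(complex_ensemble: SpeciesEnsemble,
                           receptor_ensemble: SpeciesEnsemble,
                           ligand_ensemble: SpeciesEnsemble,
                           options: FreeEnergyOptions) -> BindingEstimate:
    """Three-trajectory estimator: per-species trajectory averages of G,
    then differenced; Delta E_int is generally nonzero."""
    series = {}
    n_used = {}
    for name, ens in (("complex", complex_ensemble),
                      ("receptor", receptor_ensemble),
                      ("ligand", ligand_ensemble)):
        frames = ens.trajectory.frames[options.discard:]
        if not frames:
            raise ValueError(f"no {name} frames left after discard")
        if ens.trajectory.n_atoms != len(ens.structure):
            raise ValueError(f"{name} trajectory does not match its structure")
        series[name] = _species_series(ens.structure, ens.topology, frames,
                                       options, name)
        n_used[name] = len(frames)

    means = {}
    ses = {}
    for k in COMPONENTS:
        means[k] = float(series["complex"][k].mean()
                         - series["receptor"][k].mean()
                         - series["ligand"][k].mean())
        parts = [_se_or_none(series[s][k]) for s in ("complex", "receptor", "ligand")]
        ses[k] = (None if any(p is None for p in parts)
                  else float(np.sqrt(sum(p ** 2 for p in parts))))
    return BindingEstimate(mode="three", means=means, std_errors=ses,
                           n_frames=min(n_used.values()), discard=options.discard,
                           temperature=options.temperature)


def reorganization_energy(species: SpeciesEnsemble,
                          free_trajectory: Trajectory,
                          options: FreeEnergyOptions,
                          name: str = "species") -> ReorganizationResult:
    """Mean G_noS over in-complex conformations (evaluated as the isolated
    species) minus mean G_noS over the free ensemble."""
    if free_trajectory.n_atoms != len(species.structure):
        raise ValueError("free ensemble atom count does not match the species")
    s_in = _species_series(species.structure, species.topology,
                           species.trajectory.frames[options.discard:],
                           options, name)
    s_free = _species_series(species.structure, species.topology,
                             free_trajectory.frames[options.discard:],
                             options, name)
    return ReorganizationResult(
        species=name,
        mean_in_complex=float(s_in["g_nos"].mean()),
        mean_free=float(s_free["g_nos"].mean()),
        se_in_complex=_se_or_none(s_in["g_nos"]),
        se_free=_se_or_none(s_free["g_nos"]))


# ---------------------------------------------------------------------------
# Alanine scanning
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "H", "HN", "HA", "HA1", "HA2", "OXT"}


def mutate_to_alanine(structure: Structure, topology: Topology,
                      chain: str, resid: int
                      ) -> tuple[Structure, Topology, list[int]]:
    """Truncate a residue's side chain beyond C-beta and retype it as alanine.

    Backbone and C-beta coordinates are untouched; the topology is rebuilt
    from the parameter set carried by ``topology``.  Returns the mutated
    structure, its topology and the list of retained original atom indices
    (for mapping trajectory frames).
    """
    target = [i for i, a in enumerate(structure.atoms)
              if a.chain == chain and a.resid == resid]
    if not target:
        raise ValueError(f"residue {chain}/{resid} not found")
    resname = structure.atoms[target[0]].resname
    if resname in ("GLY", "PRO"):
        raise ValueError(f"cannot mutate {resname} {chain}/{resid} to alanine")
    if not any(structure.atoms[i].name == "CB" for i in target):
        raise ValueError(f"residue {chain}/{resid} has no C-beta")
    if topology.params is None:
        raise ValueError("topology carries no parameter set; cannot rebuild")

    kept: list[int] = []
    new_atoms = []
    for i, a in enumerate(structure.atoms):
        if i in target and a.name not in _BACKBONE and a.name != "CB":
            continue
        b = a.copy()
        if i in target:
            b.resname = "ALA"
        kept.append(i)
        new_atoms.append(b)
    mutated = Structure(new_atoms, title=structure.title)
    mutated, new_topology = assign_parameters(mutated, topology.params)
    return mutated, new_topology, kept


def _parse_mutation(label: str) -> int:
    import re
    m = re.fullmatch(r"[A-Z]?(\d+)A", label)
    if not m:
        raise ValueError(f"malformed mutation label {label!r} (expected e.g. L47A)")
    return int(m.group(1))


def alanine_scan(complex_ensemble: SpeciesEnsemble,
                 receptor_indices, ligand_indices,
                 mutations, ligand_chain: str,
                 options: FreeEnergyOptions,
                 receptor_ensemble: SpeciesEnsemble | None = None,
                 ligand_ensemble: SpeciesEnsemble | None = None
                 ) -> list[AlanineScanRow]:
    """Alanine scan over ligand mutations.

    Every frame of every ensemble is mutated identically (wild-type
    conformations are reused) and the full binding estimate recomputed.
    ``mutations`` are labels like ``"L47A"`` resolved on ``ligand_chain``.
    Runs in single mode unless receptor and ligand ensembles are supplied.
    """
    three = receptor_ensemble is not None and ligand_ensemble is not None
    if three:
        wild = binding_estimate_three(complex_ensemble, receptor_ensemble,
                                      ligand_ensemble, options)
    else:
        wild = binding_estimate_single(complex_ensemble, receptor_indices,
                                       ligand_indices, options)

    rows: list[AlanineScanRow] = []
    for label in mutations:
        resid = _parse_mutation(label)
        mut_struct, mut_topo, kept = mutate_to_alanine(
            complex_ensemble.structure, complex_ensemble.topology,
            ligand_chain, resid)
        kept_arr = np.asarray(kept, dtype=int)
        mut_traj = Trajectory([f[kept_arr] for f in complex_ensemble.trajectory.frames],
                              frame_interval=complex_ensemble.trajectory.frame_interval)
        mut_cpx = SpeciesEnsemble(mut_struct, mut_topo, mut_traj)

        old_to_new = {old: new for new, old in enumerate(kept)}
        new_rec = [old_to_new[i] for i in receptor_indices if i in old_to_new]
        new_lig = [old_to_new[i] for i in ligand_indices if i in old_to_new]

        if three:
            lig_struct_mut, lig_topo_mut, lig_kept = mutate_to_alanine(
                ligand_ensemble.structure, ligand_ensemble.topology,
                ligand_chain, resid)
            lk = np.asarray(lig_kept, dtype=int)
            lig_traj_mut = Trajectory([f[lk] for f in ligand_ensemble.trajectory.frames],
                                      frame_interval=ligand_ensemble.trajectory.frame_interval)
            est = binding_estimate_three(
                mut_cpx, receptor_ensemble,
                SpeciesEnsemble(lig_struct_mut, lig_topo_mut, lig_traj_mut),
                options)
        else:
            est = binding_estimate_single(mut_cpx, new_rec, new_lig, options)

        rows.append(AlanineScanRow(label=label, chain=ligand_chain, resid=resid,
                                   means=est.means,
                                   ddg_nos=est.dg_nos - wild.dg_nos))
    return rows


# ---------------------------------------------------------------------------
# Totals
# ---------------------------------------------------------------------------

def assemble_total(estimate: BindingEstimate, entropy_result,
                   temperature: float | None = None) -> BindingEstimate:
    """Attach -T dS terms: dG_tot = dG_noS - T dS_tot, with the -T dS values
    entering as positive additions (Table-style sign convention)."""
    t = temperature if temperature is not None else estimate.temperature
    if t is None:
        t = entropy_result.temperature
    if (estimate.temperature is not None
            and abs(entropy_result.temperature - estimate.temperature) > 1e-9):
        raise ValueError("temperature mismatch between estimate and entropy result")
    return replace(estimate,
                   minus_t_ds_rt=-t * entropy_result.ds_rt,
                   minus_t_ds_v=-t * entropy_result.ds_vib,
                   temperature=t)
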