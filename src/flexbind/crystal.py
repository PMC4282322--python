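"""Descriptor helpers for receptor-ectodomain crystal structures.

These wrap the generic geometry operations with the ectodomain conventions:
mature-protein numbering, the Val36->Glu118 / Ser340->Glu431 C-alpha anchor
vectors, and the seven-module disulfide spine of Subdomain II.  A per-file
residue-number offset is available for depositions that do not use mature
numbering.
"""

from __future__ import annotations

import numpy as np

from flexbind.geometry import (DEFAULT_ANCHOR_RESIDS, DEFAULT_DOMAIN_MAP,
                               AnchorPair, find_disulfide_modules,
                               fit_quadratic_curve, gyration_descriptors,
                               interdomain_angle, max_curvature,
                               pair_distribution)
from flexbind.structure import Structure, read_pdb

__all__ = [
    "load_receptor",
    "find_receptor_chain",
    "receptor_interdomain_angle",
    "subdomain2_curvature",
    "receptor_shape",
]

_ANCHOR_RESIDS = [r for pair in DEFAULT_ANCHOR_RESIDS for r in pair]


def find_receptor_chain(structure: Structure, resid_offset: int = 0) -> str:
    """Chain holding the receptor ectodomain: the largest chain containing
    C-alpha atoms for all four anchor residues (antibody/adnectin chains in
    co-crystals lack them)."""
    candidates: dict[str, int] = {}
    per_chain: dict[str, set[int]] = {}
    for a in structure.atoms:
        candidates[a.chain] = candidates.get(a.chain, 0) + 1
        if a.name == "CA":
            per_chain.setdefault(a.chain, set()).add(a.resid - resid_offset)
    good = [c for c, resids in per_chain.items()
            if all(r in resids for r in _ANCHOR_RESIDS)]
    if not good:
        raise ValueError("no chain contains all four anchor residues; "
                         "check the residue numbering / offset")
    return max(good, key=lambda c: candidates[c])


def load_receptor(path, chain: str | None = None,
                  resid_offset: int = 0) -> Structure:
    """Read a PDB file and return only the receptor chain (protein atoms)."""
    structure, _ = read_pdb(path)
    if chain is None:
        chain = find_receptor_chain(structure, resid_offset)
    atoms = [a.copy() for a in structure.atoms
             if a.chain == chain and a.resname not in ("HOH", "WAT")]
    for a in atoms:
        a.resid -= resid_offset
    return Structure(atoms, title=structure.title)


def receptor_interdomain_angle(receptor: Structure) -> float:
    """Subdomain I vs Subdomain III orientation angle (degrees) from the
    default C-alpha anchors."""
    chain = receptor.atoms[0].chain
    return interdomain_angle(receptor, AnchorPair.calpha(chain))


def subdomain2_curvature(receptor: Structure,
                         domain_range: tuple[int, int] | None = None,
                         sg_cutoff: float = 2.5) -> tuple[float, int]:
    """Maximum curvature (1/A) of the quadratic fit through the Subdomain-II
    disulfide-module centers of mass; returns (kappa_max, n_modules)."""
    if domain_range is None:
        domain_range = DEFAULT_DOMAIN_MAP["II"]
    modules = find_disulfide_modules(receptor, domain_range, sg_cutoff)
    if len(modules) < 3:
        raise ValueError(f"only {len(modules)} disulfide modules found in "
                         f"range {domain_range}")
    points = np.stack([m.com for m in modules])
    fit = fit_quadratic_curve(points)
    return max_curvature(fit), len(modules)


def receptor_shape(receptor: Structure, bin_width: float = 1.0):
    """Gyration descriptors and P(r) of the receptor heavy atoms."""
    coords = receptor.coords
    masses = receptor.masses
    if masses.sum() <= 0:
        masses = None
    shape = gyration_descriptors(coords, masses)
    pr = pair_distribution(coords, bin_width=bin_width, normalize=True)
    return shape, pr
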