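"""Structures, trajectories, topology and the text formats that carry them.

The PDB reader/writer speaks the fixed-column ATOM/HETATM dialect with
MODEL/ENDMDL multi-model support.  Force-field parameters travel in a small
package-defined key-value text format (see :class:`ParameterSet`); CHARMM/Amber
parameter files are deliberately not supported.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Topology",
    "ParameterSet",
    "read_pdb",
    "write_pdb",
    "read_parameters",
    "build_topology",
    "select",
]


@dataclass
class Atom:
    """One atom with coordinates and (optionally) force-field parameters."""

    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray
    icode: str = ""
    charge: float = 0.0
    mass: float = 0.0
    pb_radius: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0

    def copy(self) -> "Atom":
        return replace(self, xyz=np.array(self.xyz, dtype=float))


@dataclass
class Structure:
    """An ordered collection of atoms."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array must have shape ({len(self.atoms)}, 3)")
        for atom, row in zip(self.atoms, value):
            atom.xyz = row.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def pb_radii(self) -> np.ndarray:
        return np.array([a.pb_radius for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], title=self.title)

    def subset(self, indices) -> "Structure":
        indices = list(indices)
        if not indices:
            raise ValueError("cannot build a Structure from an empty selection")
        return Structure([self.atoms[i].copy() for i in indices], title=self.title)

    def residues(self) -> list[tuple[str, int, str, list[int]]]:
        """Group atom indices by (chain, resid, icode), preserving order."""
        out: list[tuple[str, int, str, list[int]]] = []
        key = None
        for i, a in enumerate(self.atoms):
            k = (a.chain, a.resid, a.icode)
            if k != key:
                out.append((a.chain, a.resid, a.icode, []))
                key = k
            out[-1][3].append(i)
        return out


@dataclass
class Trajectory:
    """A fixed-atom-count sequence of coordinate frames (Angstrom)."""

    frames: list[np.ndarray]
    frame_interval: float | None = None  # ns between frames, optional metadata

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory must contain at least one frame")
        n = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != n:
                raise ValueError(f"frame {i} has shape {f.shape}, expected {n}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].shape[0]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str) -> tuple[Atom, str, float]:
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    resname = line[17:21].strip()
    chain = line[21:22].strip()
    resid = int(line[22:26])
    icode = line[26:27].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    try:
        occ = float(line[54:60])
    except (ValueError, IndexError):
        occ = 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        m = re.search(r"[A-Za-z]", name)
        element = m.group(0).upper() if m else ""
    atom = Atom(name=name, element=element, resname=resname, resid=resid,
                chain=chain, icode=icode, xyz=np.array([x, y, z]))
    return atom, altloc, occ


def _resolve_altlocs(records: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep the highest-occupancy altloc per (chain, resid, icode, name); ties
    resolve to the first-listed record."""
    best: dict[tuple, tuple[float, int]] = {}
    order: list[tuple] = []
    for i, (atom, altloc, occ) in enumerate(records):
        key = (atom.chain, atom.resid, atom.icode, atom.name)
        if key not in best:
            best[key] = (occ, i)
            order.append(key)
        elif occ > best[key][0]:
            best[key] = (occ, i)
    return [records[best[k][1]][0] for k in order]


def read_pdb(path) -> tuple[Structure, Trajectory | None]:
    """Read a PDB file.

    Returns ``(structure, trajectory)``; ``trajectory`` is ``None`` unless the
    file holds two or more MODEL blocks, in which case its frames preserve
    model order.  Alternate locations keep the highest-occupancy copy
    (tie: first listed); insertion codes are preserved.
    """
    path = Path(path)
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    in_model = False
    seen_model = False
    title_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "TITLE ":
                title_parts.append(line[10:].rstrip())
            elif rec.startswith("MODEL"):
                seen_model = True
                in_model = True
                current = []
            elif rec.startswith("ENDMDL"):
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line))
    if current or not models:
        if current:
            models.append(current)
    if seen_model and in_model:
        raise ValueError(f"{path}: unterminated MODEL block")

    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")

    atom_lists = [_resolve_altlocs(m) for m in models]
    n0 = len(atom_lists[0])
    for i, al in enumerate(atom_lists):
        if len(al) != n0:
            raise ValueError(
                f"{path}: model {i + 1} has {len(al)} atoms, expected {n0}")

    structure = Structure(atom_lists[0], title=" ".join(title_parts).strip())
    trajectory = None
    if len(atom_lists) >= 2:
        frames = [np.array([a.xyz for a in al]) for al in atom_lists]
        trajectory = Trajectory(frames)
    return structure, trajectory


def _format_atom_line(i: int, a: Atom, xyz: np.ndarray) -> str:
    if a.resid > 9999 or a.resid < -999:
        raise ValueError(f"resid {a.resid} exceeds PDB 4-column capacity")
    name = a.name
    # PDB convention: 1-char element names start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    serial = min(i + 1, 99999)
    return (f"ATOM  {serial:5d} {name:<4s}{'':1s}{a.resname:<4s}"
            f"{a.chain:1s}{a.resid:4d}{a.icode:1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}\n")


def write_pdb(obj: Structure | tuple[Structure, Trajectory], path) -> None:
    """Write a Structure (or a (Structure, Trajectory) pair as multi-model)."""
    if isinstance(obj, tuple):
        structure, trajectory = obj
    else:
        structure, trajectory = obj, None
    path = Path(path)
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        if trajectory is None:
            coords = structure.coords
            for i, a in enumerate(structure.atoms):
                fh.write(_format_atom_line(i, a, coords[i]))
            fh.write("END\n")
        else:
            if trajectory.n_atoms != len(structure):
                raise ValueError("trajectory atom count does not match structure")
            for m, frame in enumerate(trajectory.frames):
                fh.write(f"MODEL     {m + 1:4d}\n")
                for i, a in enumerate(structure.atoms):
                    fh.write(_format_atom_line(i, a, frame[i]))
                fh.write("ENDMDL\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# Parameter file and topology
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Parsed contents of the package parameter format.

    File format (whitespace-separated, ``#`` comments)::

        ATOM     <resname> <atomname> <element> <charge> <mass> <pb_radius> <rmin_half> <eps>
        BOND     <resname> <atom1> <atom2> <k> <b0>
        LINK     <atomC> <atomN> <k> <b0>              # consecutive residues, same chain
        CROSS    <atomname> <atomname> <k> <b0> <cutoff>   # distance-conditional (disulfides)
        ANGLE    <center_element|*> <k> <theta0_deg>
        DIHEDRAL <elem_j|*> <elem_k|*> <k> <n> <delta_deg>
        IMPROPER <resname> <a1> <a2> <a3> <a4> <k> <psi0_deg>

    Bond/angle/improper constants are the ``k`` of ``k*(x - x0)**2``; dihedral
    terms are ``k*(1 + cos(n*phi - delta))``.
    """

    atoms: dict[tuple[str, str], tuple[str, float, float, float, float, float]] = field(default_factory=dict)
    bonds: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    links: list[tuple[str, str, float, float]] = field(default_factory=list)
    crosses: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    angles: dict[str, tuple[float, float]] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    impropers: dict[str, list[tuple[str, str, str, str, float, float]]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        ps = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                tok = line.split()
                kind = tok[0].upper()
                try:
                    if kind == "ATOM":
                        key = (tok[1], tok[2])
                        if key in ps.atoms:
                            raise ValueError(f"duplicate ATOM parameter for {key}")
                        ps.atoms[key] = (tok[3], *(float(v) for v in tok[4:9]))
                    elif kind == "BOND":
                        a1, a2 = sorted((tok[2], tok[3]))
                        key = (tok[1], a1, a2)
                        if key in ps.bonds:
                            raise ValueError(f"duplicate BOND parameter for {key}")
                        ps.bonds[key] = (float(tok[4]), float(tok[5]))
                    elif kind == "LINK":
                        ps.links.append((tok[1], tok[2], float(tok[3]), float(tok[4])))
                    elif kind == "CROSS":
                        ps.crosses.append((tok[1], tok[2], float(tok[3]),
                                           float(tok[4]), float(tok[5])))
                    elif kind == "ANGLE":
                        ps.angles[tok[1]] = (float(tok[2]), float(tok[3]))
                    elif kind == "DIHEDRAL":
                        ps.dihedrals[(tok[1], tok[2])] = (float(tok[3]), float(tok[4]),
                                                          float(tok[5]))
                    elif kind == "IMPROPER":
                        ps.impropers.setdefault(tok[1], []).append(
                            (tok[2], tok[3], tok[4], tok[5], float(tok[6]), float(tok[7])))
                    else:
                        raise ValueError(f"unknown record type {kind!r}")
                except (IndexError, ValueError) as exc:
                    if isinstance(exc, ValueError) and ("duplicate" in str(exc)
                                                        or "unknown" in str(exc)):
                        raise
                    raise ValueError(f"{path}:{lineno}: malformed {kind} record") from exc
        return ps

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (rn, an), (el, q, m, r, rm, ep) in self.atoms.items():
                fh.write(f"ATOM {rn} {an} {el} {q:.6f} {m:.4f} {r:.4f} {rm:.4f} {ep:.6f}\n")
            for (rn, a1, a2), (k, b0) in self.bonds.items():
                fh.write(f"BOND {rn} {a1} {a2} {k:.3f} {b0:.4f}\n")
            for a1, a2, k, b0 in self.links:
                fh.write(f"LINK {a1} {a2} {k:.3f} {b0:.4f}\n")
            for a1, a2, k, b0, cut in self.crosses:
                fh.write(f"CROSS {a1} {a2} {k:.3f} {b0:.4f} {cut:.3f}\n")
            for el, (k, t0) in self.angles.items():
                fh.write(f"ANGLE {el} {k:.3f} {t0:.3f}\n")
            for (e1, e2), (k, n, d) in self.dihedrals.items():
                fh.write(f"DIHEDRAL {e1} {e2} {k:.4f} {n:.1f} {d:.3f}\n")
            for rn, rows in self.impropers.items():
                for a1, a2, a3, a4, k, p0 in rows:
                    fh.write(f"IMPROPER {rn} {a1} {a2} {a3} {a4} {k:.3f} {p0:.3f}\n")


@dataclass
class Topology:
    """Bonded terms, index-based, plus nonbonded exclusions.

    ``bonds``: (i, j, k, b0); ``angles``: (i, j, k, k_theta, theta0_deg);
    ``dihedrals``: (i, j, k, l, k_phi, n, delta_deg);
    ``impropers``: (i, j, k, l, k_psi, psi0_deg).
    ``excluded``: 1-2 and 1-3 pairs (i < j) dropped from nonbonded sums;
    ``pairs14``: 1-4 pairs flagged (included at full strength by default).
    """

    n_atoms: int
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, float, float]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int, float, float]] = field(default_factory=list)
    excluded: set[tuple[int, int]] = field(default_factory=set)
    pairs14: set[tuple[int, int]] = field(default_factory=set)
    params: ParameterSet | None = None

    def __post_init__(self) -> None:
        seen = set()
        for i, j, *_ in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"bond ({i},{j}) index out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"bond {key} appears more than once")
            seen.add(key)

    def bond_graph(self) -> dict[int, set[int]]:
        g: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j, *_ in self.bonds:
            g[i].add(j)
            g[j].add(i)
        return g


def exclusions_from_bonds(n_atoms: int, bond_pairs) -> tuple[set, set]:
    """1-2 and 1-3 exclusion pairs plus flagged 1-4 pairs from a bond list."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for i, j in bond_pairs:
        adj[i].add(j)
        adj[j].add(i)
    excluded: set[tuple[int, int]] = set()
    pairs14: set[tuple[int, int]] = set()
    for i, j in bond_pairs:
        excluded.add((min(i, j), max(i, j)))
    for j in range(n_atoms):
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            excluded.add((min(i, k), max(i, k)))
    for j, k in bond_pairs:
        for i in adj[j] - {k}:
            for m in adj[k] - {j}:
                if i != m:
                    pairs14.add((min(i, m), max(i, m)))
        for i in adj[k] - {j}:
            for m in adj[j] - {k}:
                if i != m:
                    pairs14.add((min(i, m), max(i, m)))
    pairs14 -= excluded
    return excluded, pairs14


def build_topology(structure: Structure, params: ParameterSet) -> Topology:
    """Construct bonds/angles/dihedrals/impropers and exclusions for a
    parameterized structure."""
    index: dict[tuple[str, int, str, str], int] = {}
    for i, a in enumerate(structure.atoms):
        index[(a.chain, a.resid, a.icode, a.name)] = i

    bond_pairs: list[tuple[int, int]] = []
    bonds: list[tuple[int, int, float, float]] = []

    def add_bond(i: int, j: int, k: float, b0: float) -> None:
        bond_pairs.append((i, j))
        bonds.append((i, j, k, b0))

    residues = structure.residues()
    res_atoms: list[dict[str, int]] = []
    for chain, resid, icode, idxs in residues:
        res_atoms.append({structure.atoms[i].name: i for i in idxs})

    # intra-residue bonds
    for (chain, resid, icode, idxs), names in zip(residues, res_atoms):
        resname = structure.atoms[idxs[0]].resname
        for (rn, a1, a2), (k, b0) in params.bonds.items():
            if rn == resname and a1 in names and a2 in names:
                add_bond(names[a1], names[a2], k, b0)

    # peptide-style links between consecutive residues of the same chain
    for r in range(len(residues) - 1):
        c1, i1, _, _ = residues[r]
        c2, i2, _, _ = residues[r + 1]
        if c1 != c2 or i2 != i1 + 1:
            continue
        for a1, a2, k, b0 in params.links:
            if a1 in res_atoms[r] and a2 in res_atoms[r + 1]:
                add_bond(res_atoms[r][a1], res_atoms[r + 1][a2], k, b0)

    # distance-conditional cross bonds (disulfides)
    coords = structure.coords
    for a1, a2, k, b0, cutoff in params.crosses:
        cand = [i for i, a in enumerate(structure.atoms) if a.name in (a1, a2)]
        partner: dict[int, int] = {}
        for i, j in itertools.combinations(cand, 2):
            ai, aj = structure.atoms[i], structure.atoms[j]
            if (ai.chain, ai.resid, ai.icode) == (aj.chain, aj.resid, aj.icode):
                continue
            if {ai.name, aj.name} != {a1, a2} and not (a1 == a2 and ai.name == a1):
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                for x in (i, j):
                    if x in partner:
                        raise ValueError(
                            f"atom {structure.atoms[x].chain}/{structure.atoms[x].resid}"
                            f"/{structure.atoms[x].name} matched to two cross-bond partners")
                partner[i] = j
                partner[j] = i
                add_bond(i, j, k, b0)

    adj: dict[int, set[int]] = {i: set() for i in range(len(structure))}
    for i, j in bond_pairs:
        adj[i].add(j)
        adj[j].add(i)

    def elem(i: int) -> str:
        return structure.atoms[i].element

    def angle_param(j: int) -> tuple[float, float]:
        p = params.angles.get(elem(j), params.angles.get("*"))
        if p is None:
            a = structure.atoms[j]
            raise ValueError(f"no ANGLE parameter for center ({a.resname}, {a.name})")
        return p

    angles: list[tuple[int, int, int, float, float]] = []
    for j in range(len(structure)):
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            ka, t0 = angle_param(j)
            angles.append((i, j, k, ka, t0))

    dihedrals: list[tuple[int, int, int, int, float, float, float]] = []
    if params.dihedrals:
        for j, k in bond_pairs:
            p = (params.dihedrals.get((elem(j), elem(k)))
                 or params.dihedrals.get((elem(k), elem(j)))
                 or params.dihedrals.get(("*", "*")))
            if p is None:
                continue
            kd, n, delta = p
            for i in sorted(adj[j] - {k}):
                for m in sorted(adj[k] - {j}):
                    if i != m:
                        dihedrals.append((i, j, k, m, kd, n, delta))

    impropers: list[tuple[int, int, int, int, float, float]] = []
    for (chain, resid, icode, idxs), names in zip(residues, res_atoms):
        resname = structure.atoms[idxs[0]].resname
        for a1, a2, a3, a4, k, p0 in params.impropers.get(resname, []):
            if all(a in names for a in (a1, a2, a3, a4)):
                impropers.append((names[a1], names[a2], names[a3], names[a4], k, p0))

    excluded, pairs14 = exclusions_from_bonds(len(structure), bond_pairs)
    return Topology(n_atoms=len(structure), bonds=bonds, angles=angles,
                    dihedrals=dihedrals, impropers=impropers,
                    excluded=excluded, pairs14=pairs14, params=params)


def read_parameters(path, structure: Structure) -> tuple[Structure, Topology]:
    """Assign per-atom parameters from a parameter file and build the topology.

    Every atom must be covered by an ATOM record keyed on (resname, atomname);
    an uncovered atom raises a ``ValueError`` naming it.
    """
    params = ParameterSet.from_file(path)
    return assign_parameters(structure, params)


def assign_parameters(structure: Structure, params: ParameterSet) -> tuple[Structure, Topology]:
    out = structure.copy()
    for a in out.atoms:
        key = (a.resname, a.name)
        if key not in params.atoms:
            raise ValueError(f"no parameters for atom ({a.resname}, {a.name})")
        el, q, m, r, rm, ep = params.atoms[key]
        a.element = el
        a.charge = q
        a.mass = m
        a.pb_radius = r
        a.lj_rmin_half = rm
        a.lj_epsilon = ep
    topology = build_topology(out, params)
    return out, topology


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    """Recursive-descent parser for the small selection language.

    Grammar: ``expr := term (('or') term)*``; ``term := factor (('and') factor)*``;
    ``factor := 'not' factor | '(' expr ')' | primitive``.
    Primitives: ``all``, ``chain <id>...``, ``resid <n | a:b | a-b>...``,
    ``resname <name>...``, ``name <name>...``, ``element <el>...``.
    """

    KEYWORDS = {"and", "or", "not", "(", ")"}
    FIELDS = {"chain", "resid", "resname", "name", "element"}

    def __init__(self, expression: str):
        self.tokens = _TOKEN_RE.findall(expression)
        self.pos = 0
        if not self.tokens:
            raise ValueError("empty selection expression")

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r} in selection")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "or":
            self.next()
            rhs = self.term()
            node = ("or", node, rhs)
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "and":
            self.next()
            rhs = self.factor()
            node = ("and", node, rhs)
        return node

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.next()
            return ("not", self.factor())
        if tok == "(":
            self.next()
            node = self.expr()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return node
        return self.primitive()

    def primitive(self):
        tok = self.next()
        if tok == "all":
            return ("all",)
        if tok is None or tok.lower() not in self.FIELDS:
            raise ValueError(f"malformed selection near {tok!r}")
        fieldname = tok.lower()
        values = []
        while self.peek() is not None and self.peek() not in self.KEYWORDS \
                and self.peek().lower() not in self.FIELDS:
            values.append(self.next())
        if not values:
            raise ValueError(f"selection keyword {fieldname!r} needs at least one value")
        return (fieldname, values)


def _eval_node(node, atom: Atom) -> bool:
    op = node[0]
    if op == "all":
        return True
    if op == "and":
        return _eval_node(node[1], atom) and _eval_node(node[2], atom)
    if op == "or":
        return _eval_node(node[1], atom) or _eval_node(node[2], atom)
    if op == "not":
        return not _eval_node(node[1], atom)
    values = node[1]
    if op == "resid":
        for v in values:
            m = re.fullmatch(r"(-?\d+)[:–-](-?\d+)", v)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo <= atom.resid <= hi:
                    return True
            elif re.fullmatch(r"-?\d+", v):
                if atom.resid == int(v):
                    return True
            else:
                raise ValueError(f"malformed resid token {v!r}")
        return False
    attr = {"chain": atom.chain, "resname": atom.resname,
            "name": atom.name, "element": atom.element}[op]
    return any(attr == v for v in values)


def select(structure: Structure, expression: str) -> list[int]:
    """Resolve a selection expression to an ordered atom-index list."""
    tree = _SelParser(expression).parse()
    return [i for i, a in enumerate(structure.atoms) if _eval_node(tree, a)]
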