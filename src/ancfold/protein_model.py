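"""Coarse torsional protein model.

A protein with ``n`` residues is modelled as a linkage in which only the
backbone dihedrals phi and psi are flexible; bond lengths, bond angles and
the omega dihedral are fixed at ideal values.  A conformation is therefore a
vector of ``2n`` angles (degrees, residue-major ``phi_0, psi_0, phi_1, ...``),
and forward kinematics realizes it as Cartesian coordinates with six atoms
per residue in the fixed order ``N, H, CA, CB, C, O`` (glycine carries HA in
the CB slot).

Conventions
-----------
* Angles are stored in degrees, normalized to the half-open interval
  (-180, 180].
* The first residue's phi and the last residue's psi are geometrically
  undefined; they are stored as the placeholder 180 deg and excluded from
  perturbation.
* The first residue is placed in a canonical frame (N at the origin, CA on
  the +x axis, C in the xy half-plane with y > 0), so raw coordinates are
  only comparable between conformations of the same topology; rigid-motion
  invariant comparison goes through least-RMSD superposition.
"""

from __future__ import annotations

import itertools
import uuid
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Segment",
    "ProteinTopology",
    "Conformation",
    "CoordinateSet",
    "ATOM_NAMES",
    "HYDROPHOBIC_RESIDUES",
    "normalize_angle",
    "dihedral",
    "forward_kinematics",
    "backbone_torsions_from_coords",
    "perturb",
    "read_native_pdb",
    "write_conformations",
    "read_conformations",
    "write_pdb",
]

# Atom slots per residue; glycine's CB slot holds HA.
ATOM_NAMES = ("N", "H", "CA", "CB", "C", "O")
N_SLOT, H_SLOT, CA_SLOT, CB_SLOT, C_SLOT, O_SLOT = range(6)

# Ideal internal coordinates (Angstrom / degrees), standard peptide values.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = 122.5  # fixed chirality convention for the CB marker
OMEGA = 180.0

TERMINAL_PLACEHOLDER = 180.0

# Apolar residues (Kyte-Doolittle hydropathy > 0); drives the E_hp contact term.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "CYS", "PHE", "ILE", "LEU", "MET", "VAL"}
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructuralError(ValueError):
    """Topology/conformation shape mismatch or malformed input structure."""


def normalize_angle(angle):
    """Normalize angles (degrees) to (-180, 180].  Idempotent; array-safe."""
    a = np.asarray(angle, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Segment:
    """A native secondary-structure segment over a half-open residue range."""

    label: str
    kind: str  # "helix" or "strand"
    start: int
    end: int  # exclusive

    def __post_init__(self):
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"segment kind must be helix/strand, got {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment range [{self.start}, {self.end})")

    @property
    def residues(self) -> range:
        return range(self.start, self.end)


@dataclass(frozen=True)
class ProteinTopology:
    """Immutable chain description: sequence, hydrophobicity, native state."""

    sequence: tuple
    hydrophobic: tuple
    native_torsions: np.ndarray
    native_segments: tuple = ()

    def __post_init__(self):
        n = len(self.sequence)
        if n < 2:
            raise ValueError("a chain needs at least 2 residues")
        torsions = normalize_angle(np.asarray(self.native_torsions, dtype=float))
        if torsions.shape != (2 * n,):
            raise StructuralError(
                f"native_torsions has shape {torsions.shape}, expected ({2 * n},)"
            )
        object.__setattr__(self, "native_torsions", torsions)
        object.__setattr__(self, "sequence", tuple(self.sequence))
        object.__setattr__(self, "hydrophobic", tuple(bool(h) for h in self.hydrophobic))
        if len(self.hydrophobic) != n:
            raise StructuralError("hydrophobic flags must match residue count")
        segs = tuple(self.native_segments)
        for s in segs:
            if not (0 <= s.start < s.end <= n):
                raise ValueError(f"segment {s.label} outside chain [0, {n})")
        for a, b in itertools.combinations(segs, 2):
            if a.start < b.end and b.start < a.end:
                raise ValueError(f"segments {a.label} and {b.label} overlap")
        object.__setattr__(self, "native_segments", segs)

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def n_torsions(self) -> int:
        return 2 * self.n

    def flexible_indices(self) -> np.ndarray:
        """Torsion indices that carry a defined dihedral (excludes the two
        terminal placeholders)."""
        return np.arange(1, 2 * self.n - 1)

    def native_conformation(self) -> "Conformation":
        return Conformation(torsions=self.native_torsions.copy(), id="native")


def _fresh_id() -> str:
    return uuid.uuid4().hex[:12]


@dataclass
class Conformation:
    """A point in torsion space with lazily cached energy and rigidity map."""

    torsions: np.ndarray
    id: str = field(default_factory=_fresh_id)
    energy: Optional[float] = None
    rigidity_map: Optional[object] = None

    def __post_init__(self):
        self.torsions = normalize_angle(np.asarray(self.torsions, dtype=float))

    def with_id(self, new_id: str) -> "Conformation":
        return replace(self, id=new_id)


@dataclass(frozen=True)
class CoordinateSet:
    """Cartesian realization: 6n atom positions (Angstrom), residue-major."""

    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] % 6 != 0:
            raise StructuralError(f"coords must be (6n, 3), got {c.shape}")
        object.__setattr__(self, "coords", c)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0] // 6


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    x = np.dot(c12, c23)
    y = np.dot(np.cross(c12, c23), b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(y, x)))


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: position D bonded to C with given internal coords
    (angle B-C-D, torsion A-B-C-D)."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-np.cos(theta) * bc + np.sin(theta) * np.cos(phi) * m
                + np.sin(theta) * np.sin(phi) * n)
    return c + d


def forward_kinematics(topo: ProteinTopology, conf: Conformation) -> CoordinateSet:
    """Realize a torsion vector as 6n Cartesian coordinates.

    Deterministic: identical torsions give bitwise-identical coordinates.
    The first residue sits in the canonical frame documented at module level.
    """
    n = topo.n
    t = conf.torsions
    if t.shape != (2 * n,):
        raise StructuralError(
            f"conformation has {t.shape[0]} torsions, topology expects {2 * n}"
        )
    coords = np.zeros((6 * n, 3))

    # Backbone chain N-CA-C per residue, linked by the peptide bond.
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array((-np.cos(ang), np.sin(ang), 0.0))
    for i in range(1, n):
        psi_prev = t[2 * (i - 1) + 1]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        phi_i = t[2 * i]
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i)

    for i in range(n):
        base = 6 * i
        coords[base + N_SLOT] = N[i]
        coords[base + CA_SLOT] = CA[i]
        coords[base + C_SLOT] = C[i]
        # Amide H: anti to the following CA across the (planar) peptide bond;
        # first residue uses a fixed convention in the local frame.
        if i == 0:
            coords[base + H_SLOT] = _place(C[0], CA[0], N[0], BOND_N_H,
                                           ANGLE_C_N_H, TERMINAL_PLACEHOLDER)
        else:
            coords[base + H_SLOT] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_H,
                                           ANGLE_C_N_H, 0.0)
        # Carbonyl O: anti to the next amide N; last residue uses the stored
        # psi placeholder.
        psi_i = t[2 * i + 1]
        coords[base + O_SLOT] = _place(N[i], CA[i], C[i], BOND_C_O,
                                       ANGLE_CA_C_O, normalize_angle(psi_i + 180.0))
        # CB marker (HA for glycine) with a fixed improper-torsion convention.
        bond = BOND_CA_CB if topo.sequence[i] != "GLY" else 1.090
        coords[base + CB_SLOT] = _place(N[i], C[i], CA[i], bond,
                                        ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
    return CoordinateSet(coords=coords)


def backbone_torsions_from_coords(coords: CoordinateSet) -> np.ndarray:
    """Measure phi/psi from coordinates (inverse of forward kinematics on the
    backbone).  Terminal undefined dihedrals get the 180 deg placeholder."""
    n = coords.n_residues
    c = coords.coords
    t = np.full(2 * n, TERMINAL_PLACEHOLDER)
    for i in range(n):
        Ni, CAi, Ci = c[6 * i + N_SLOT], c[6 * i + CA_SLOT], c[6 * i + C_SLOT]
        if i > 0:
            Cprev = c[6 * (i - 1) + C_SLOT]
            t[2 * i] = dihedral(Cprev, Ni, CAi, Ci)
        if i < n - 1:
            Nnext = c[6 * (i + 1) + N_SLOT]
            t[2 * i + 1] = dihedral(Ni, CAi, Ci, Nnext)
    return normalize_angle(t)


def perturb(conf: Conformation, indices, magnitude: float, rng: np.random.Generator,
            new_id: Optional[str] = None) -> Conformation:
    """Perturb the given torsion indices uniformly within +/- magnitude.

    Returns a fresh conformation (new id, energy and rigidity reset); all
    other torsions are untouched.
    """
    idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
    if idx.size == 0:
        raise ValueError("perturb requires a non-empty torsion index set")
    if magnitude <= 0:
        raise ValueError("perturb magnitude must be > 0")
    if idx.min() < 0 or idx.max() >= conf.torsions.shape[0]:
        raise StructuralError("torsion index out of range")
    torsions = conf.torsions.copy()
    torsions[idx] = normalize_angle(
        torsions[idx] + rng.uniform(-magnitude, magnitude, size=idx.size)
    )
    return Conformation(torsions=torsions, id=new_id or _fresh_id())


# ---------------------------------------------------------------------------
# PDB input / output and the columnar conformation file
# ---------------------------------------------------------------------------

def _segments_from_header(lines, resseq_to_index) -> tuple:
    segs = []
    h = s = 0
    for line in lines:
        rec = line[:6]
        if rec == "HELIX ":
            start, end = int(line[21:25]), int(line[33:37])
            h += 1
            label = f"a{h}"
            kind = "helix"
        elif rec == "SHEET ":
            start, end = int(line[22:26]), int(line[33:37])
            s += 1
            label = f"b{s}"
            kind = "strand"
        else:
            continue
        if start in resseq_to_index and end in resseq_to_index:
            segs.append(Segment(label=label, kind=kind,
                                start=resseq_to_index[start],
                                end=resseq_to_index[end] + 1))
    return tuple(segs)


def read_native_pdb(path) -> ProteinTopology:
    """Build a topology from a single-chain PDB file.

    phi/psi come from the backbone (N, CA, C) dihedrals; hydrophobic flags
    from the apolar-residue table; segments from HELIX/SHEET records when
    present.  Multi-model files use the first model (logged).
    """
    import logging

    from Bio.PDB import PDBParser

    with open(path) as fh:
        lines = fh.readlines()

    structure = PDBParser(QUIET=True).get_structure("native", path)
    models = list(structure.get_models())
    if len(models) > 1:
        logging.getLogger(__name__).info(
            "PDB file %s has %d models; using the first", path, len(models))
    chain = next(models[0].get_chains())

    residues: dict = {}
    order: list = []
    for res in chain.get_residues():
        if res.id[0] != " ":
            continue  # skip heteroatoms/waters
        resseq = res.id[1]
        residues[resseq] = {"resname": res.get_resname()}
        for atom in res.get_atoms():
            residues[resseq][atom.get_name()] = atom.get_coord().astype(float)
        order.append(resseq)

    if len(order) < 2:
        raise StructuralError("PDB file must contain at least 2 residues")

    for resseq in order:
        missing = [a for a in ("N", "CA", "C") if a not in residues[resseq]]
        if missing:
            raise StructuralError(
                f"residue {resseq} is missing backbone atom(s): {', '.join(missing)}"
            )

    n = len(order)
    torsions = np.full(2 * n, TERMINAL_PLACEHOLDER)
    for i, resseq in enumerate(order):
        r = residues[resseq]
        if i > 0:
            prev = residues[order[i - 1]]
            torsions[2 * i] = dihedral(prev["C"], r["N"], r["CA"], r["C"])
        if i < n - 1:
            nxt = residues[order[i + 1]]
            torsions[2 * i + 1] = dihedral(r["N"], r["CA"], r["C"], nxt["N"])

    sequence = tuple(residues[q]["resname"] for q in order)
    hydrophobic = tuple(res in HYDROPHOBIC_RESIDUES for res in sequence)
    resseq_to_index = {q: i for i, q in enumerate(order)}
    segments = _segments_from_header(lines, resseq_to_index)
    return ProteinTopology(sequence=sequence, hydrophobic=hydrophobic,
                           native_torsions=torsions, native_segments=segments)


def write_pdb(path, topo: ProteinTopology, confs: Sequence[Conformation],
              segments_header: bool = True) -> None:
    """Write conformations as (multi-)model PDB with the 6-atom model."""
    out = []
    if segments_header:
        for k, seg in enumerate(topo.native_segments, start=1):
            if seg.kind == "helix":
                out.append(
                    f"HELIX  {k:>3} {k:>3} {topo.sequence[seg.start]:>3} A "
                    f"{seg.start + 1:>4}  {topo.sequence[seg.end - 1]:>3} A "
                    f"{seg.end:>4}  1{'':>30}{seg.end - seg.start:>6}"
                )
            else:
                out.append(
                    f"SHEET  {k:>3} {'S':>3} 1 {topo.sequence[seg.start]:>3} A"
                    f"{seg.start + 1:>4}  {topo.sequence[seg.end - 1]:>3} A"
                    f"{seg.end:>4}  0"
                )
    multi = len(confs) > 1
    for mi, conf in enumerate(confs, start=1):
        if multi:
            out.append(f"MODEL     {mi:>4}")
        coords = forward_kinematics(topo, conf).coords
        serial = 1
        for i, res in enumerate(topo.sequence):
            for slot, name in enumerate(ATOM_NAMES):
                label = "HA" if (name == "CB" and res == "GLY") else name
                x, y, z = coords[6 * i + slot]
                elem = label[0]
                out.append(
                    f"ATOM  {serial:>5} {label:<4} {res:>3} A{i + 1:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2}"
                )
                serial += 1
        if multi:
            out.append("ENDMDL")
    out.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def write_conformations(path, confs: Sequence[Conformation]) -> None:
    """Columnar text format: one row per conformation (id, 2n torsions, energy)."""
    with open(path, "w") as fh:
        for conf in confs:
            e = "unset" if conf.energy is None else repr(float(conf.energy))
            tors = " ".join(repr(float(x)) for x in conf.torsions)
            fh.write(f"{conf.id} {tors} {e}\n")


def read_conformations(path) -> list:
    confs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            cid = parts[0]
            energy = None if parts[-1] == "unset" else float(parts[-1])
            torsions = np.array([float(x) for x in parts[1:-1]])
            confs.append(Conformation(torsions=torsions, id=cid, energy=energy))
    return confs
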