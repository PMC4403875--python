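"""Backbone torsions, amide-hydrogen placement, and ideal peptide building.

The builder extends a chain atom-by-atom from internal coordinates (bond
length, bond angle, torsion) — the natural-extension-reference-frame
construction.  Built peptides are capped with an N-terminal acetyl (ACE)
and a C-terminal N-methylamide (NME) so that every residue, including the
termini, has phi/psi defined and hydrogen-bonding partners on both sides —
the capped-oligopeptide construction used for ideal model helices.

Angles are degrees at every interface; radians appear only inside the
trigonometric kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .structure_io import AtomRecord, Chain, Residue, Structure, write_pdb

__all__ = [
    "TorsionTriple",
    "GeometrySet",
    "GEOMETRY_SETS",
    "GeometryError",
    "dihedral",
    "bond_angle",
    "place_atom",
    "backbone_torsions",
    "place_amide_hydrogens",
    "build_peptide",
    "generate_fixture_archive",
    "CHAIN_BREAK_CN",
    "CHAIN_BREAK_CACA",
]

# chain-break thresholds: peptide C-N above 2.0 A or CA-CA above 4.5 A
CHAIN_BREAK_CN = 2.0
CHAIN_BREAK_CACA = 4.5

AMINO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_KNOWN3 = set(AMINO3.values())

# improper dihedral N-C-CA-CB for the L-configuration
_CB_IMPROPER = 120.0


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear reference points)."""


@dataclass(frozen=True)
class TorsionTriple:
    """(phi, psi, omega) in degrees; omega is the amide torsion preceding
    the residue.  None marks an undefined angle (terminus or chain break)."""

    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float] = 180.0

    def __post_init__(self) -> None:
        for value in (self.phi, self.psi, self.omega):
            if value is not None and not (-180.0 < value <= 180.0):
                raise ValueError(f"torsion {value} outside (-180, 180]")


@dataclass(frozen=True)
class GeometrySet:
    """Covalent backbone geometry used by the builder (lengths A, angles deg)."""

    name: str
    n_ca: float
    ca_c: float
    c_n: float
    c_o: float
    n_h: float
    ang_n_ca_c: float
    ang_ca_c_n: float
    ang_c_n_ca: float
    ang_ca_c_o: float
    ca_cb: float = 1.530
    ang_c_ca_cb: float = 110.1

    def __post_init__(self) -> None:
        for length in (self.n_ca, self.ca_c, self.c_n, self.c_o, self.n_h, self.ca_cb):
            if not 0.8 < length < 2.0:
                raise ValueError(f"bond length {length} outside (0.8, 2.0) A")
        for angle in (self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca,
                      self.ang_ca_c_o, self.ang_c_ca_cb):
            if not 90 < angle < 135:
                raise ValueError(f"bond angle {angle} outside (90, 135) deg")


#: Engh & Huber restraint values, the standard crystallographic geometry;
#: "pauling" differs in the angle at the alpha carbon, provided because
#: residues-per-turn is sensitive primarily to that angle.
GEOMETRY_SETS: dict[str, GeometrySet] = {
    "engh_huber": GeometrySet(
        name="engh_huber",
        n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231, n_h=1.00,
        ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7, ang_ca_c_o=120.8,
    ),
    "pauling": GeometrySet(
        name="pauling",
        n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231, n_h=1.00,
        ang_n_ca_c=110.0, ang_ca_c_n=116.2, ang_c_n_ca=121.7, ang_ca_c_o=120.8,
    ),
}


# -- vector kernels ---------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in (-180, 180], IUPAC right-handed convention.

    Zero for a cis (eclipsed) arrangement, 180 for trans.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise GeometryError("coincident consecutive points")
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear consecutive points")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


def bond_angle(p1, p2, p3) -> float:
    """Angle at p2 in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, float(cosang)))))


def place_atom(a, b, c, length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C with |C-D| = length, angle(B,C,D) = angle
    and dihedral(A,B,C,D) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-10:
        raise GeometryError("coincident frame points")
    bc = bc / nbc
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference frame for atom placement")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        length * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# -- torsion extraction -----------------------------------------------------

def _pos(residue: Optional[Residue], name: str) -> Optional[np.ndarray]:
    if residue is None:
        return None
    atom = residue.get(name)
    return None if atom is None else np.asarray(atom.position)


def _is_break(prev: Residue, curr: Residue) -> bool:
    c = _pos(prev, "C")
    n = _pos(curr, "N")
    if c is not None and n is not None:
        return bool(np.linalg.norm(n - c) > CHAIN_BREAK_CN)
    ca1 = _pos(prev, "CA") if prev.name != "ACE" else _pos(prev, "CH3")
    ca2 = _pos(curr, "CA") if curr.name != "NME" else _pos(curr, "CH3")
    if ca1 is not None and ca2 is not None:
        return bool(np.linalg.norm(ca2 - ca1) > CHAIN_BREAK_CACA)
    return True  # connectivity cannot be verified


def backbone_torsions(chain: Chain) -> list[TorsionTriple]:
    """Per-residue (phi, psi, omega), None across breaks and at termini.

    phi_i   = C_{i-1} - N_i - CA_i - C_i
    psi_i   = N_i - CA_i - C_i - N_{i+1}
    omega_i = CA_{i-1} - C_{i-1} - N_i - CA_i   (amide preceding residue i)

    Capping groups (ACE/NME) serve as dihedral partners but do not get
    entries of their own; the ACE methyl stands in for its alpha carbon.
    """
    residues = chain.residues
    aa_idx = [i for i, r in enumerate(residues) if r.name in _KNOWN3]
    triples: list[TorsionTriple] = []
    for idx in aa_idx:
        residue = residues[idx]
        prev = residues[idx - 1] if idx > 0 else None
        nxt = residues[idx + 1] if idx + 1 < len(residues) else None
        if prev is not None and _is_break(prev, residue):
            prev = None
        if nxt is not None and _is_break(residue, nxt):
            nxt = None

        n, ca, c = _pos(residue, "N"), _pos(residue, "CA"), _pos(residue, "C")
        c_prev = _pos(prev, "C")
        ca_prev = _pos(prev, "CH3") if prev is not None and prev.name == "ACE" else _pos(prev, "CA")
        n_next = _pos(nxt, "N")

        phi = psi = omega = None
        try:
            if all(p is not None for p in (c_prev, n, ca, c)):
                phi = dihedral(c_prev, n, ca, c)
            if all(p is not None for p in (n, ca, c, n_next)):
                psi = dihedral(n, ca, c, n_next)
            if all(p is not None for p in (ca_prev, c_prev, n, ca)):
                omega = dihedral(ca_prev, c_prev, n, ca)
        except GeometryError:
            phi = psi = omega = None
        triples.append(TorsionTriple(phi, psi, omega))
    return triples


# -- hydrogen placement -----------------------------------------------------

def place_amide_hydrogens(structure: Structure, nh_length: float = 1.00) -> Structure:
    """Add backbone amide hydrogens in place and return the structure.

    H sits in the C_{i-1}, N_i, CA_i plane along the external bisector of
    the C-N-CA angle at ``nh_length`` from N — planar sp2 nitrogen
    geometry.  Proline and chain-start residues receive no H.  The NME cap
    (a donor) is treated like a residue with its methyl standing in for CA.
    """
    for chain in structure.chains:
        residues = chain.residues
        for idx, residue in enumerate(residues):
            if residue.name in ("PRO", "ACE") or "H" in residue:
                continue
            prev = residues[idx - 1] if idx > 0 else None
            if prev is None or _is_break(prev, residue):
                continue
            n = _pos(residue, "N")
            ca = _pos(residue, "CH3") if residue.name == "NME" else _pos(residue, "CA")
            c_prev = _pos(prev, "C")
            if n is None or ca is None or c_prev is None:
                continue
            to_c = c_prev - n
            to_ca = ca - n
            to_c /= np.linalg.norm(to_c)
            to_ca /= np.linalg.norm(to_ca)
            direction = -(to_c + to_ca)
            norm = np.linalg.norm(direction)
            if norm < 1e-10:
                continue
            h = n + direction / norm * nh_length
            residue.atoms["H"] = AtomRecord(
                serial=0, name="H", altloc="", residue_name=residue.name,
                chain_id=chain.chain_id, residue_seq=residue.seq,
                insertion_code=residue.insertion_code,
                position=(float(h[0]), float(h[1]), float(h[2])),
                occupancy=1.0, element="H",
            )
    return structure


# -- peptide building -------------------------------------------------------

def _norm_code(code: str) -> str:
    code = code.upper()
    if len(code) == 1:
        if code not in AMINO3:
            raise ValueError(f"unknown residue code {code!r}")
        return AMINO3[code]
    if code not in _KNOWN3:
        raise ValueError(f"unknown residue code {code!r}")
    return code


def build_peptide(
    sequence: Sequence[str] | str,
    torsions: Sequence[TorsionTriple | tuple],
    geometry: GeometrySet | str = "engh_huber",
    caps: bool = True,
    chain_id: str = "A",
    add_hydrogens: bool = True,
) -> Structure:
    """Build an ideal peptide from backbone torsions.

    Parameters
    ----------
    sequence
        Residue codes (one- or three-letter); only backbone atoms plus CB
        (for non-glycine) are built, so any standard code is accepted.
    torsions
        One (phi, psi, omega) triple per residue; omega is the amide
        preceding the residue and defaults to 180 (trans).  Undefined
        entries fall back to ideal helical values.
    geometry
        A :class:`GeometrySet` or the name of a registered set.
    caps
        Flank the chain with ACE (acceptor-only) and NME (donor-only)
        capping groups, realizing phi of the first and psi of the last
        residue.

    Recomputing :func:`backbone_torsions` on the result reproduces the
    inputs to numerical precision; the construction is deterministic.
    """
    if isinstance(geometry, str):
        geometry = GEOMETRY_SETS[geometry]
    g = geometry
    codes = [_norm_code(c) for c in sequence]
    if len(torsions) != len(codes):
        raise ValueError("torsions length must equal sequence length")
    triples = [t if isinstance(t, TorsionTriple) else TorsionTriple(*t) for t in torsions]
    phis = [(-57.0 if t.phi is None else t.phi) for t in triples]
    psis = [(-47.0 if t.psi is None else t.psi) for t in triples]
    omegas = [(180.0 if t.omega is None else t.omega) for t in triples]

    chain = Chain(chain_id)
    structure = Structure(entry_id="BLT", chains=[chain])

    def add_atom(residue: Residue, name: str, pos, element: str) -> None:
        residue.atoms[name] = AtomRecord(
            serial=0, name=name, altloc="", residue_name=residue.name,
            chain_id=chain_id, residue_seq=residue.seq, insertion_code="",
            position=(float(pos[0]), float(pos[1]), float(pos[2])),
            occupancy=1.0, element=element,
        )

    # ---- seed frame --------------------------------------------------
    # Either the ACE cap (CH3-C=O) or a bare N-CA start, laid in the
    # xy-plane; everything downstream follows from internal coordinates.
    dummy = np.array([0.0, -1.0, 0.0])
    if caps:
        ace = Residue("ACE", 0)
        chain.residues.append(ace)
        ch3 = np.zeros(3)
        c_prev = np.array([1.510, 0.0, 0.0])  # methyl-carbonyl bond
        add_atom(ace, "CH3", ch3, "C")
        add_atom(ace, "C", c_prev, "C")
        ca_prev = ch3          # stands in for CA in the omega frame
        n_ref = dummy          # torsion reference for placing N_1
        psi_prev = 0.0         # arbitrary: fixes N_1 in the xy-plane
    else:
        ca_prev = c_prev = None

    n_prev = None
    o_frames: list[tuple[Residue, np.ndarray, np.ndarray, np.ndarray, float]] = []

    for i, code in enumerate(codes):
        residue = Residue(code, i + 1)
        chain.residues.append(residue)
        if c_prev is None:
            # uncapped N-terminus: fixed frame, phi_1 unrealized
            n = np.zeros(3)
            ca = np.array([g.n_ca, 0.0, 0.0])
            ang = math.radians(180.0 - g.ang_n_ca_c)
            c = ca + g.ca_c * np.array([math.cos(ang), math.sin(ang), 0.0])
        else:
            n = place_atom(n_ref, ca_prev, c_prev, g.c_n, g.ang_ca_c_n, psi_prev)
            ca = place_atom(ca_prev, c_prev, n, g.n_ca, g.ang_c_n_ca, omegas[i])
            c = place_atom(c_prev, n, ca, g.ca_c, g.ang_n_ca_c, phis[i])
        add_atom(residue, "N", n, "N")
        add_atom(residue, "CA", ca, "C")
        add_atom(residue, "C", c, "C")
        if code != "GLY":
            cb = place_atom(n, c, ca, g.ca_cb, g.ang_c_ca_cb, _CB_IMPROPER)
            add_atom(residue, "CB", cb, "C")
        # carbonyl O goes trans to the next N: dihedral(N,CA,C,O) = psi+180
        o_frames.append((residue, n, ca, c, psis[i]))

        n_ref, ca_prev, c_prev, psi_prev = n, ca, c, psis[i]
        n_prev = n

    if caps:
        nme = Residue("NME", len(codes) + 1)
        chain.residues.append(nme)
        n_nme = place_atom(n_ref, ca_prev, c_prev, g.c_n, g.ang_ca_c_n, psi_prev)
        ch3_nme = place_atom(ca_prev, c_prev, n_nme, 1.450, g.ang_c_n_ca, 180.0)
        add_atom(nme, "N", n_nme, "N")
        add_atom(nme, "CH3", ch3_nme, "C")

    # carbonyl oxygens: anti to the following amide nitrogen
    for residue, n, ca, c, psi in o_frames:
        o = place_atom(n, ca, c, g.c_o, g.ang_ca_c_o, psi + 180.0)
        add_atom(residue, "O", o, "O")
    if caps:
        # ACE carbonyl oxygen, planar amide, anti to N_1
        n1 = np.asarray(chain.residues[1].atoms["N"].position)
        ch3 = np.asarray(ace.atoms["CH3"].position)
        c_ace = np.asarray(ace.atoms["C"].position)
        o_ace = place_atom(n1, ch3, c_ace, g.c_o, g.ang_ca_c_o, 180.0)
        add_atom(ace, "O", o_ace, "O")

    if add_hydrogens:
        place_amide_hydrogens(structure, g.n_h)
    return structure


# -- fixture archive --------------------------------------------------------

def generate_fixture_archive(
    spec: Sequence[tuple],
    out_dir: str | Path,
    length: int = 12,
    geometry: GeometrySet | str = "engh_huber",
) -> list[Path]:
    """Write one capped poly-alanine PDB file per (label, torsions, resolution).

    ``torsions`` may be a (phi, psi) pair applied uniformly to ``length``
    residues, or an explicit per-residue list of triples.  The assigned
    nominal resolution is emitted as a REMARK 2 record so the files behave
    like a miniature local structure archive for survey runs.  Output is
    deterministic; duplicate labels are rejected.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [entry[0] for entry in spec]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels in fixture spec")
    written: list[Path] = []
    for label, torsions, resolution in spec:
        if not 0 <= resolution < 5.0:
            raise ValueError(f"nominal resolution {resolution} outside [0, 5)")
        if (isinstance(torsions, (tuple, list)) and len(torsions) == 2
                and all(isinstance(v, (int, float)) for v in torsions)):
            phi, psi = torsions
            triples = [TorsionTriple(phi, psi, 180.0)] * length
        else:
            triples = list(torsions)
        structure = build_peptide("A" * len(triples), triples, geometry=geometry)
        structure.entry_id = str(label)[:4].upper()
        structure.resolution = float(resolution)
        path = out_dir / f"{label}.pdb"
        path.write_text(write_pdb(structure))
        written.append(path)
    return written
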