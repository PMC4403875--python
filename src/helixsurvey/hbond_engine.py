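"""Geometric backbone hydrogen-bond detection and helix assignment.

A backbone hydrogen bond is an amide N-H donating to a carbonyl C=O.
Detection is purely geometric and deliberately permissive — every donor /
acceptor pair inside the distance and angle cutoffs is kept, with no
exclusivity constraint, so one N-H may donate to two carbonyls at once
(a three-centered, or bifurcated, hydrogen bond).  Helices are then
assigned from the pattern of i->i+3 / i->i+4 bonds: a helix needs at
least two consecutive helical hydrogen bonds, the shortest pattern being
i->i+3 followed by i+1->i+4.

Register convention: a bond is reported acceptor-side, "i -> i+k" meaning
the carbonyl of residue i accepts from the amide of residue i+k; register
= donor_seq - acceptor_seq for same-chain bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .backbone_geometry import bond_angle
from .structure_io import Structure

__all__ = [
    "HBondCriteria",
    "HBond",
    "HelixSegment",
    "MissingHydrogensError",
    "detect_hbonds",
    "classify_hbonds",
    "find_shared",
    "assign_helices",
    "analyze_structure",
    "bonds_to_rows",
    "BOND_TSV_HEADER",
]

HELICAL_REGISTERS = (3, 4)

CATEGORIES = ("alpha", "three_ten", "sheet", "turn", "bend", "coil", "disallowed")


class MissingHydrogensError(ValueError):
    """Structure has no amide hydrogens; call place_amide_hydrogens first."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs for backbone N-H...O=C detection.

    Defaults are permissive, suited to the solvent-shielded interior of a
    helix where i->i+3 contacts near 2.8-3.0 A are genuine (if weak)
    hydrogen bonds: H...A 3.0 A, D...A 3.9 A, and both the D-H...A and
    H...A=C angles at least 90 deg (planar-feasible, no linearity
    requirement).
    """

    max_ha: float = 3.0
    max_da: float = 3.9
    min_dha: float = 90.0
    min_hac: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.max_ha < self.max_da:
            raise ValueError("criteria require 0 < max_ha < max_da")
        for angle in (self.min_dha, self.min_hac):
            if not 0 <= angle <= 180:
                raise ValueError("angle cutoffs must lie in [0, 180]")


@dataclass(frozen=True)
class HBond:
    """One detected backbone hydrogen bond (acceptor i -> donor i+register)."""

    donor_chain: str
    donor_seq: int
    acceptor_chain: str
    acceptor_seq: int
    d_ha: float
    d_da: float
    angle_dha: float
    angle_hac: float
    category: Optional[str] = None
    shared: bool = False

    @property
    def same_chain(self) -> bool:
        return self.donor_chain == self.acceptor_chain

    @property
    def register(self) -> Optional[int]:
        """acceptor -> donor sequence separation, None for interchain bonds."""
        if not self.same_chain:
            return None
        return self.donor_seq - self.acceptor_seq

    @property
    def helical(self) -> bool:
        return self.register in HELICAL_REGISTERS


@dataclass
class HelixSegment:
    """Maximal run of consecutive helical hydrogen bonds on one chain."""

    chain: str
    start: int
    end: int
    bonds: list[HBond] = field(default_factory=list)

    @property
    def flavor(self) -> str:
        registers = {b.register for b in self.bonds}
        if registers == {4}:
            return "alpha"
        if registers == {3}:
            return "three_ten"
        return "mixed"


def _donors(structure: Structure):
    """Yield (chain_id, seq, N, H) for every amide that can donate.

    Proline has no amide proton; the ACE cap is acceptor-only.
    """
    for chain in structure.chains:
        for residue in chain.residues:
            if residue.name in ("PRO", "ACE"):
                continue
            n, h = residue.get("N"), residue.get("H")
            if n is None or h is None:
                continue
            yield chain.chain_id, residue.seq, np.asarray(n.position), np.asarray(h.position)


def _acceptors(structure: Structure):
    """Yield (chain_id, seq, O, C) for every backbone carbonyl (NME has none)."""
    for chain in structure.chains:
        for residue in chain.residues:
            o, c = residue.get("O"), residue.get("C")
            if o is None or c is None:
                continue
            yield chain.chain_id, residue.seq, np.asarray(o.position), np.asarray(c.position)


def detect_hbonds(
    structure: Structure, criteria: HBondCriteria = HBondCriteria()
) -> list[HBond]:
    """Detect every backbone N-H...O=C pair meeting all four criteria.

    No exclusivity: a donor may appear in several bonds.  Pairs with
    |register| < 2 on the same chain are excluded (bonded neighbours).
    Raises :class:`MissingHydrogensError` when the structure carries no
    amide hydrogens at all.
    """
    donors = list(_donors(structure))
    acceptors = list(_acceptors(structure))
    if not donors:
        raise MissingHydrogensError(
            "no amide hydrogens found; run place_amide_hydrogens first"
        )
    bonds: list[HBond] = []
    acc_pos = np.array([a[2] for a in acceptors]) if acceptors else np.empty((0, 3))
    for d_chain, d_seq, n_pos, h_pos in donors:
        if len(acc_pos) == 0:
            break
        d_da_all = np.linalg.norm(acc_pos - n_pos, axis=1)
        for j in np.nonzero(d_da_all <= criteria.max_da)[0]:
            a_chain, a_seq, o_pos, c_pos = acceptors[j]
            if a_chain == d_chain and abs(d_seq - a_seq) < 2:
                continue
            d_ha = float(np.linalg.norm(o_pos - h_pos))
            if d_ha > criteria.max_ha:
                continue
            angle_dha = bond_angle(n_pos, h_pos, o_pos)
            if angle_dha < criteria.min_dha:
                continue
            angle_hac = bond_angle(h_pos, o_pos, c_pos)
            if angle_hac < criteria.min_hac:
                continue
            bonds.append(
                HBond(
                    donor_chain=d_chain,
                    donor_seq=d_seq,
                    acceptor_chain=a_chain,
                    acceptor_seq=a_seq,
                    d_ha=round(d_ha, 6),
                    d_da=round(float(d_da_all[j]), 6),
                    angle_dha=round(angle_dha, 6),
                    angle_hac=round(angle_hac, 6),
                )
            )
    bonds.sort(key=lambda b: (b.donor_chain, b.donor_seq, b.acceptor_chain, b.acceptor_seq))
    return bonds


def assign_helices(bonds: Sequence[HBond]) -> list[HelixSegment]:
    """Assign helix segments from the i->i+3 / i->i+4 bond pattern.

    Helical-register bonds are grouped by chain and ordered by acceptor
    residue; a maximal run of bonds whose acceptors sit at consecutive
    residues, of length >= 2, becomes a segment (the shortest legal
    pattern: i->i+3 followed by i+1->i+4).  Isolated helical-register
    bonds form no segment.
    """
    segments: list[HelixSegment] = []
    by_chain: dict[str, dict[int, list[HBond]]] = {}
    for bond in bonds:
        if bond.helical:
            by_chain.setdefault(bond.donor_chain, {}).setdefault(
                bond.acceptor_seq, []
            ).append(bond)
    for chain_id, by_acceptor in by_chain.items():
        seqs = sorted(by_acceptor)
        run: list[int] = []
        for seq in seqs + [None]:  # sentinel flushes the last run
            if run and (seq is None or seq != run[-1] + 1):
                if len(run) >= 2:
                    run_bonds = [b for s in run for b in by_acceptor[s]]
                    start = run[0]
                    end = max(b.donor_seq for b in run_bonds)
                    segments.append(
                        HelixSegment(chain=chain_id, start=start, end=end, bonds=run_bonds)
                    )
                run = []
            if seq is not None:
                run.append(seq)
    segments.sort(key=lambda s: (s.chain, s.start))
    return segments


def classify_hbonds(
    bonds: Sequence[HBond],
    segments: Optional[Sequence[HelixSegment]] = None,
) -> list[HBond]:
    """Assign every detected bond exactly one category.

    Decision ladder, applied in order:

    1. helical register (+3/+4) inside an assigned segment -> alpha /
       three_ten;
    2. |register| >= 5 or interchain, with at least one ladder-consistent
       neighbour (donor+-1 or acceptor+-1 bonded across the same pairing)
       -> sheet;
    3. helical register outside any segment (isolated) -> turn;
    4. register +-2 -> bend;
    5. remaining intrachain bonds -> coil.

    ``disallowed`` is reserved for the strict-audit pathway (bonds failing
    an angle cutoff by < 10 deg), produced by :func:`audit_disallowed`.
    """
    if segments is None:
        segments = assign_helices(bonds)
    in_segment: set[tuple] = set()
    for segment in segments:
        for bond in segment.bonds:
            in_segment.add(_bond_key(bond))

    # neighbour index for the sheet-ladder test
    pair_set = {
        (b.donor_chain, b.donor_seq, b.acceptor_chain, b.acceptor_seq) for b in bonds
    }

    def has_ladder_neighbour(b: HBond) -> bool:
        for dd, da in ((1, 1), (-1, -1), (1, -1), (-1, 1), (0, 2), (0, -2), (2, 0), (-2, 0)):
            if (b.donor_chain, b.donor_seq + dd, b.acceptor_chain, b.acceptor_seq + da) in pair_set:
                return True
        return False

    out: list[HBond] = []
    for bond in bonds:
        register = bond.register
        if bond.helical and _bond_key(bond) in in_segment:
            category = "alpha" if register == 4 else "three_ten"
        elif (register is None or abs(register) >= 5) and has_ladder_neighbour(bond):
            category = "sheet"
        elif bond.helical:
            category = "turn"
        elif register is not None and abs(register) == 2:
            category = "bend"
        else:
            category = "coil"
        out.append(replace(bond, category=category))
    return out


def _bond_key(bond: HBond) -> tuple:
    return (bond.donor_chain, bond.donor_seq, bond.acceptor_chain, bond.acceptor_seq)


def find_shared(bonds: Sequence[HBond]) -> list[HBond]:
    """Flag three-centered (bifurcated) helical bonds.

    A bond is shared iff its donor N-H also forms a detected bond at the
    other helical register — an i->i+3 paired with an i->i+4 from the same
    donor, both classified helical.  Both members are flagged.  A donor
    bonded at a helical and a non-helical register is generic bifurcation,
    not a shared helical bond.
    """
    helical_by_donor: dict[tuple, set[int]] = {}
    for bond in bonds:
        if bond.category in ("alpha", "three_ten"):
            helical_by_donor.setdefault((bond.donor_chain, bond.donor_seq), set()).add(
                bond.register
            )
    out: list[HBond] = []
    for bond in bonds:
        registers = helical_by_donor.get((bond.donor_chain, bond.donor_seq), set())
        shared = (
            bond.category in ("alpha", "three_ten")
            and {3, 4} <= registers
        )
        out.append(replace(bond, shared=shared))
    return out


def audit_disallowed(
    structure: Structure,
    criteria: HBondCriteria,
    margin: float = 10.0,
) -> list[HBond]:
    """Strict-audit pathway: near-miss bonds failing an angle cutoff by < margin.

    These pass both distance cutoffs but miss min_dha or min_hac by less
    than ``margin`` degrees; they are categorized ``disallowed``.
    """
    relaxed = HBondCriteria(
        max_ha=criteria.max_ha,
        max_da=criteria.max_da,
        min_dha=max(0.0, criteria.min_dha - margin),
        min_hac=max(0.0, criteria.min_hac - margin),
    )
    strict_keys = {_bond_key(b) for b in detect_hbonds(structure, criteria)}
    near = [
        replace(b, category="disallowed")
        for b in detect_hbonds(structure, relaxed)
        if _bond_key(b) not in strict_keys
    ]
    return near


def analyze_structure(
    structure: Structure,
    criteria: HBondCriteria = HBondCriteria(),
    strict_audit: bool = False,
) -> tuple[list[HBond], list[HelixSegment]]:
    """Full per-structure pipeline: detect, assign helices, classify, flag shared.

    Returns the categorized bond list (shared bonds flagged) and the helix
    segments.  With ``strict_audit``, near-miss bonds are appended with
    category ``disallowed``.
    """
    bonds = detect_hbonds(structure, criteria)
    segments = assign_helices(bonds)
    bonds = classify_hbonds(bonds, segments)
    bonds = find_shared(bonds)
    if strict_audit:
        bonds = bonds + audit_disallowed(structure, criteria)
    return bonds, segments


BOND_TSV_HEADER = (
    "entry\tchain\tdonor\tacceptor\tregister\td_HA\td_DA\tangle_DHA\tangle_HAC"
    "\tcategory\tshared"
)


def bonds_to_rows(entry_id: str, bonds: Iterable[HBond]) -> list[str]:
    """One TSV row per bond, matching BOND_TSV_HEADER."""
    rows = []
    for b in bonds:
        register = b.register if b.register is not None else "interchain"
        rows.append(
            f"{entry_id}\t{b.donor_chain}\t{b.donor_seq}\t{b.acceptor_seq}\t{register}"
            f"\t{b.d_ha:.3f}\t{b.d_da:.3f}\t{b.angle_dha:.1f}\t{b.angle_hac:.1f}"
            f"\t{b.category}\t{int(b.shared)}"
        )
    return rows
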