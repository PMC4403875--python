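"""Read and write PDB-format coordinate files.

Exposes a minimal hierarchical model (Structure -> Chain -> Residue ->
Atom) tailored to backbone hydrogen-bond analysis: only model 1 is kept,
alternate locations are collapsed to the highest-occupancy conformer,
waters are dropped, and the nominal crystallographic resolution is read
from the REMARK 2 record.  Coordinates are never modified on input.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "ResolutionBin",
    "PDBFormatError",
    "EmptyStructureError",
    "parse_pdb",
    "write_pdb",
    "default_resolution_bins",
    "assign_resolution_bin",
]

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}


class PDBFormatError(ValueError):
    """A fixed-column record could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(ValueError):
    """Raised when a stream holds no ATOM records or a structure is empty."""


@dataclass
class AtomRecord:
    """One ATOM/HETATM record after altloc resolution."""

    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    element: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinate for atom {self.name}")


@dataclass
class Residue:
    name: str
    seq: int
    insertion_code: str = ""
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq, self.insertion_code)

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms

    def __getitem__(self, atom_name: str) -> AtomRecord:
        return self.atoms[atom_name]

    def get(self, atom_name: str) -> Optional[AtomRecord]:
        return self.atoms.get(atom_name)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    entry_id: str = ""
    resolution: Optional[float] = None
    method: Optional[str] = None
    chains: list[Chain] = field(default_factory=list)
    source_model: int = 1

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for residue in chain:
                yield chain, residue

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())


@dataclass(frozen=True)
class ResolutionBin:
    """Half-open resolution interval [low, high) in angstroms."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("resolution bin requires low < high")

    @property
    def label(self) -> str:
        return f"{self.low:.2f}–{self.high - 0.01:.2f}"

    def __contains__(self, resolution: float) -> bool:
        return self.low <= resolution < self.high


def default_resolution_bins() -> list[ResolutionBin]:
    """Ten 0.5-angstrom bins tiling [0, 5): 0.00-0.49 ... 4.50-4.99."""
    return [ResolutionBin(0.5 * i, 0.5 * (i + 1)) for i in range(10)]


def assign_resolution_bin(
    resolution: Optional[float], bins: Sequence[ResolutionBin]
) -> Optional[ResolutionBin]:
    """Return the unique bin with low <= resolution < high, or None.

    None is returned both for absent resolutions (NMR-style entries) and
    for resolutions beyond the last bin edge.
    """
    if resolution is None:
        return None
    if resolution < 0:
        raise ValueError(f"negative resolution: {resolution}")
    for b in bins:
        if resolution in b:
            return b
    return None


# -- parsing ----------------------------------------------------------------

_RESOLUTION_RE = re.compile(r"RESOLUTION\.\s+(\d+\.?\d*)\s+ANGSTROM")


def _parse_atom_line(line: str, line_number: int) -> AtomRecord:
    # PDB v3.3 fixed columns (1-based): serial 7-11, name 13-16, altloc 17,
    # resName 18-20, chainID 22, resSeq 23-26, iCode 27, x 31-38, y 39-46,
    # z 47-54, occupancy 55-60, element 77-78.
    if len(line) < 54:
        raise PDBFormatError("ATOM record shorter than coordinate fields", line_number)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_seq = int(line[22:26])
        insertion_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed fixed-column record: {exc}", line_number) from None
    if not element:
        element = _guess_element(name)
    return AtomRecord(
        serial=serial,
        name=name,
        altloc=altloc,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_seq=residue_seq,
        insertion_code=insertion_code,
        position=(x, y, z),
        occupancy=occupancy,
        element=element,
    )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "HD" and atom_name[:1].isdigit():
        return "H"
    if stripped.startswith(("CL", "BR", "FE", "ZN", "MG", "NA", "MN")):
        return stripped[:2].capitalize()
    return stripped[0]


def parse_pdb(text: str | Iterable[str], entry_id: str = "") -> Structure:
    """Parse a PDB-format character stream into a Structure.

    Only MODEL 1 is read; altlocs are collapsed to the highest-occupancy
    conformer (ties broken by lexicographically first altloc identifier);
    waters are skipped; other HETATM records are ignored except the ACE
    and NME capping groups, which take part in backbone hydrogen bonding.

    Raises :class:`EmptyStructureError` when no ATOM record survives and
    :class:`PDBFormatError` (with line number) on malformed records.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    resolution: Optional[float] = None
    method: Optional[str] = None
    model_number = 0
    in_wanted_model = True
    source_model = 1
    # candidate atoms per (chain, resseq, icode, atom name) keyed for altloc pick
    chains: dict[str, Chain] = {}
    residue_index: dict[tuple[str, int, str], Residue] = {}

    for i, line in enumerate(lines, start=1):
        record = line[:6]
        if record == "MODEL ":
            try:
                model_number = int(line[6:].split()[0])
            except (ValueError, IndexError):
                raise PDBFormatError("malformed MODEL record", i) from None
            in_wanted_model = model_number in (0, 1)
            if in_wanted_model:
                source_model = max(model_number, 1)
        elif record == "ENDMDL":
            in_wanted_model = False
        elif record.startswith("REMARK") and line[6:10].strip() == "2":
            m = _RESOLUTION_RE.search(line)
            if m:
                resolution = float(m.group(1))
        elif record == "EXPDTA":
            method = line[6:].strip() or None
        elif record == "HEADER" and not entry_id:
            entry_id = line[62:66].strip()
        elif record in ("ATOM  ", "HETATM"):
            if not in_wanted_model:
                continue
            atom = _parse_atom_line(line, i)
            if atom.residue_name in _WATER_NAMES:
                continue
            if record == "HETATM" and atom.residue_name not in ("ACE", "NME"):
                continue
            key = (atom.chain_id, atom.residue_seq, atom.insertion_code)
            residue = residue_index.get(key)
            if residue is None:
                chain = chains.setdefault(atom.chain_id, Chain(atom.chain_id))
                residue = Residue(atom.residue_name, atom.residue_seq, atom.insertion_code)
                chain.residues.append(residue)
                residue_index[key] = residue
            existing = residue.atoms.get(atom.name)
            if existing is None or _altloc_preferred(atom, existing):
                residue.atoms[atom.name] = atom

    if not residue_index:
        raise EmptyStructureError("no ATOM records found in stream")

    structure = Structure(
        entry_id=entry_id,
        resolution=resolution,
        method=method,
        chains=list(chains.values()),
        source_model=source_model,
    )
    for chain in structure.chains:
        chain.residues.sort(key=lambda r: (r.seq, r.insertion_code))
    return structure


def _altloc_preferred(candidate: AtomRecord, incumbent: AtomRecord) -> bool:
    """Highest occupancy wins; tie broken by lexicographically first altloc."""
    if candidate.occupancy != incumbent.occupancy:
        return candidate.occupancy > incumbent.occupancy
    return candidate.altloc < incumbent.altloc


# -- writing ----------------------------------------------------------------

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} exceeds PDB field width")
    # single-letter elements are right-padded starting at column 14
    if len(name) < 4 and len(element) < 2:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure to PDB format (coordinates to 3 decimals)."""
    if not structure.chains or structure.n_atoms == 0:
        raise EmptyStructureError("cannot write an empty structure")
    out: list[str] = []
    if structure.resolution is not None:
        out.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:5.2f} ANGSTROMS."
        )
    else:
        out.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    serial = 0
    for chain in structure.chains:
        for residue in chain.residues:
            record = "ATOM  " if residue.name in _STANDARD_RESIDUES else "HETATM"
            for atom in residue.atoms.values():
                serial += 1
                x, y, z = atom.position
                out.append(
                    f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' '}"
                    f"{residue.name:>3s} {chain.chain_id}{residue.seq:4d}"
                    f"{residue.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        last = chain.residues[-1]
        out.append(
            f"TER   {serial:5d}      {last.name:>3s} {chain.chain_id}{last.seq:4d}"
        )
    out.append("END")
    return "\n".join(out) + "\n"
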