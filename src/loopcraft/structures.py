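"""Minimal protein structure model with PDB reading and writing.

The data model is deliberately small: atoms carry a name, an element, a
position and an occupancy; residues carry author numbering (with insertion
codes) and their atoms; a structure is an ordered set of chains plus a
separate list of ligand (HETATM) groups.  Alternate locations are resolved
at parse time to a single conformer, waters are dropped, and only the first
MODEL of a multi-model file is read — the conventions used throughout the
loop-feature pipeline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "parse_structure",
    "chain_sequence",
    "write_structure",
    "AA3_TO_1",
    "STANDARD_AA1",
]

STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: three-letter → one-letter mapping; nonstandard residues with a standard
#: parent map to that parent, everything else becomes 'X'.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues → parent amino acid
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "MLY": "K",
    "CSO": "C", "CME": "C", "OCS": "C", "PTR": "Y", "SEP": "S",
    "TPO": "T", "KCX": "K", "LLP": "K", "CSD": "C", "FME": "M",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name3: str
    chain_id: str
    seq_index: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa1(self) -> str:
        return AA3_TO_1.get(self.name3, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_index, self.icode)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not found in structure {self.id!r}") from None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for ch in self.chains.values() for r in ch)

    def residues(self):
        for ch in self.chains.values():
            yield from ch

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    raw = line[lo:hi].strip()
    try:
        return float(raw)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {raw!r}"
        ) from None


def parse_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A'); waters are dropped; other HETATM
    groups are kept as ligands; only the first MODEL is read.
    """
    # raw atoms keyed by residue, with altloc retained for later resolution
    chain_order: list[str] = []
    residues: dict[tuple[str, int, str], Residue] = {}
    res_order: list[tuple[str, int, str]] = []
    raw: dict[tuple, list[tuple[str, Atom]]] = {}
    het_keys: set[tuple[str, int, str]] = set()
    n_atom_records = 0
    in_first_model = True
    seen_model = False

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            if seen_model:
                in_first_model = False
            seen_model = True
            continue
        if rec.startswith("ENDMDL"):
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        name3 = line[17:20].strip()
        if name3 in _WATER_NAMES:
            continue
        if rec == "ATOM  ":
            n_atom_records += 1
        name = line[12:16].strip()
        altloc = line[16].strip()
        chain_id = line[21].strip() or "A"
        try:
            seq_index = int(line[22:26])
        except ValueError:
            raise PDBParseError(f"line {lineno}: malformed residue number {line[22:26]!r}")
        icode = line[26].strip()
        x = _parse_float(line, 30, 38, "x coordinate", lineno)
        y = _parse_float(line, 38, 46, "y coordinate", lineno)
        z = _parse_float(line, 46, 54, "z coordinate", lineno)
        occ_raw = line[54:60].strip()
        occ = float(occ_raw) if occ_raw else 1.0
        element = line[76:78].strip() or _guess_element(name)

        is_polymer = rec == "ATOM  " or name3 in AA3_TO_1
        rkey = (chain_id, seq_index, icode)
        if rkey not in residues:
            residues[rkey] = Residue(name3=name3, chain_id=chain_id,
                                     seq_index=seq_index, icode=icode)
            res_order.append(rkey)
            if is_polymer and chain_id not in chain_order:
                chain_order.append(chain_id)
        if not is_polymer:
            het_keys.add(rkey)
        akey = (rkey, name)
        atom = Atom(name=name, element=element, position=np.array([x, y, z]),
                    occupancy=occ)
        raw.setdefault(akey, []).append((altloc, atom))

    if n_atom_records == 0:
        raise PDBParseError("no ATOM records found")

    # altloc resolution: highest occupancy wins, ties -> altloc 'A'
    for (rkey, _name), variants in raw.items():
        variants.sort(key=lambda t: (-t[1].occupancy, t[0] != "A", t[0]))
        residues[rkey].atoms.append(variants[0][1])

    s = Structure(id=structure_id)
    for rkey in res_order:
        res = residues[rkey]
        if rkey in het_keys:
            s.ligands.append(res)
        else:
            s.chains.setdefault(res.chain_id, []).append(res)
    for ch in s.chains.values():
        ch.sort(key=lambda r: (r.seq_index, r.icode))
    if not any(s.chains.values()):
        raise PDBParseError("no chain residues found (HETATM-only input)")
    return s


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit():  # e.g. 1HB
        return "H"
    if len(stripped) >= 2 and stripped[:2] in ("FE", "ZN", "MG", "MN", "CA") and stripped == stripped[:2]:
        return stripped[:2].capitalize()
    return stripped[0]


def chain_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain; nonstandard residues become 'X'."""
    return "".join(r.aa1 for r in s.chain(chain_id))


def _format_atom(serial: int, a: Atom, r: Residue, het: bool) -> str:
    name = a.name
    # PDB atom-name justification: 1-char elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{serial % 100000:5d} {name:<4s}{'':1s}{r.name3:>3s} "
        f"{r.chain_id:1s}{r.seq_index:4d}{r.icode or ' ':1s}   "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_structure(s: Structure) -> str:
    """Serialize a Structure back to PDB text (coordinates to 3 decimals)."""
    if not any(s.chains.values()):
        raise ValueError("cannot write an empty structure")
    lines: list[str] = []
    serial = 1
    for chain_id in s.chains:
        for r in s.chains[chain_id]:
            for a in r.atoms:
                lines.append(_format_atom(serial, a, r, het=False))
                serial += 1
        lines.append(f"TER   {serial % 100000:5d}      "
                     f"{s.chains[chain_id][-1].name3:>3s} {chain_id:1s}"
                     f"{s.chains[chain_id][-1].seq_index:4d}")
        serial += 1
    for r in s.ligands:
        for a in r.atoms:
            lines.append(_format_atom(serial, a, r, het=True))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
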