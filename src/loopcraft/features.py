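"""Per-position structural features of a loop window.

For every residue of a candidate loop the pipeline records backbone
dihedrals (phi, psi), the number of van der Waals contacts between heavy
atoms within 5.0 A, and geometric hydrogen bonds (donor/acceptor heavy-atom
pairs within 3.5 A).  Contacts internal to the loop and contacts between
the loop and the rest of the fold are counted separately; hydrogen bonds
are additionally split into donor and acceptor roles.

Contacts exclude atom pairs within one residue and pairs between
sequence-adjacent residues, so covalent geometry never counts as an
interaction.  Donors and acceptors are assigned from a fixed per-residue
chemistry table (backbone N donates except in proline, backbone O accepts,
side chains per residue type); the criterion is distance-only because
crystal structures generally lack hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure, Residue

__all__ = [
    "PositionFeatures",
    "LoopInstance",
    "VDW_RADIUS",
    "HBOND_RADIUS",
    "compute_dihedrals",
    "count_vdw_contacts",
    "detect_hbonds",
    "extract_loop_features",
    "dihedral_angle",
]

VDW_RADIUS = 5.0   # A, heavy-atom contact radius
HBOND_RADIUS = 3.5  # A, donor-acceptor effective radius
PEPTIDE_BOND_MAX = 2.0  # A, C(i)-N(i+1) distance accepted as a real bond

# side-chain donor / acceptor heavy atoms per residue type
_SC_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "TRP": ["NE1"], "HIS": ["ND1", "NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "ASN": ["ND2"], "GLN": ["NE2"],
}
_SC_ACCEPTORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "ASN": ["OD1"], "GLN": ["OE1"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
}


@dataclass
class PositionFeatures:
    phi: float | None = None
    psi: float | None = None
    vdw_intra: int = 0
    vdw_external: int = 0
    hbond_donor_intra: int = 0
    hbond_donor_external: int = 0
    hbond_acceptor_intra: int = 0
    hbond_acceptor_external: int = 0
    flagged: bool = False  # set where backbone is incomplete or broken

    @property
    def vdw_total(self) -> int:
        return self.vdw_intra + self.vdw_external

    @property
    def hbond_donor_total(self) -> int:
        return self.hbond_donor_intra + self.hbond_donor_external

    @property
    def hbond_acceptor_total(self) -> int:
        return self.hbond_acceptor_intra + self.hbond_acceptor_external

    def to_dict(self) -> dict:
        return {
            "phi": self.phi, "psi": self.psi,
            "vdw_intra": self.vdw_intra, "vdw_external": self.vdw_external,
            "hbond_donor_intra": self.hbond_donor_intra,
            "hbond_donor_external": self.hbond_donor_external,
            "hbond_acceptor_intra": self.hbond_acceptor_intra,
            "hbond_acceptor_external": self.hbond_acceptor_external,
            "flagged": self.flagged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PositionFeatures":
        return cls(**d)


@dataclass
class LoopInstance:
    """A fixed-length loop window of one chain with per-position features."""

    structure_id: str
    chain_id: str
    start: int  # 0-based offset into the chain residue list
    sequence: str
    features: list[PositionFeatures] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features and len(self.features) != len(self.sequence):
            raise ValueError("sequence and features must have equal length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def source_id(self) -> str:
        return f"{self.structure_id}/{self.chain_id}:{self.start}"

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id, "chain_id": self.chain_id,
            "start": self.start, "sequence": self.sequence,
            "features": [f.to_dict() for f in self.features],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoopInstance":
        return cls(
            structure_id=d["structure_id"], chain_id=d["chain_id"],
            start=d["start"], sequence=d["sequence"],
            features=[PositionFeatures.from_dict(f) for f in d["features"]],
        )


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _bonded(prev: Residue, nxt: Residue) -> bool:
    c = prev.atom("C")
    n = nxt.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.position - n.position)) <= PEPTIDE_BOND_MAX


def compute_dihedrals(s: Structure) -> dict[str, list[tuple[float | None, float | None]]]:
    """Backbone (phi, psi) per residue for every chain.

    phi is undefined at the chain N-terminus and across chain breaks
    (peptide C-N distance above 2.0 A), psi analogously at the C-terminus.
    """
    out: dict[str, list[tuple[float | None, float | None]]] = {}
    for chain_id, residues in s.chains.items():
        angles: list[tuple[float | None, float | None]] = []
        for i, r in enumerate(residues):
            n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
            phi = psi = None
            if n is not None and ca is not None and c is not None:
                if i > 0 and _bonded(residues[i - 1], r):
                    pc = residues[i - 1].atom("C")
                    phi = dihedral_angle(pc.position, n.position,
                                         ca.position, c.position)
                if i + 1 < len(residues) and _bonded(r, residues[i + 1]):
                    nn = residues[i + 1].atom("N")
                    psi = dihedral_angle(n.position, ca.position,
                                         c.position, nn.position)
            angles.append((phi, psi))
        out[chain_id] = angles
    return out


def _check_window(s: Structure, chain_id: str, start: int, length: int) -> list[Residue]:
    residues = s.chain(chain_id)
    if start < 0 or length < 1 or start + length > len(residues):
        raise IndexError(
            f"window [{start}, {start + length}) out of range for chain "
            f"{chain_id!r} with {len(residues)} residues")
    return residues


def _heavy_atom_table(s: Structure):
    """Flat arrays of heavy-atom coordinates with owning-residue bookkeeping."""
    coords: list[np.ndarray] = []
    owner: list[tuple[str, int]] = []  # (chain_id, index within chain)
    for chain_id, residues in s.chains.items():
        for idx, r in enumerate(residues):
            for a in r.atoms:
                if not a.is_hydrogen:
                    coords.append(a.position)
                    owner.append((chain_id, idx))
    return np.array(coords), owner


def _adjacent(o1: tuple[str, int], o2: tuple[str, int]) -> bool:
    return o1[0] == o2[0] and abs(o1[1] - o2[1]) <= 1


def count_vdw_contacts(s: Structure, chain_id: str, start: int,
                       length: int, radius: float = VDW_RADIUS
                       ) -> list[tuple[int, int]]:
    """(intra, external) heavy-atom contact counts per loop position.

    Counts atom pairs within `radius`; pairs inside one residue or between
    sequence-adjacent residues are excluded.  Ligand atoms are ignored.
    """
    _check_window(s, chain_id, start, length)
    coords, owner = _heavy_atom_table(s)
    in_loop = {(chain_id, i) for i in range(start, start + length)}
    intra = np.zeros(length, dtype=int)
    external = np.zeros(length, dtype=int)
    if len(coords) == 0:
        return list(zip(intra.tolist(), external.tolist()))
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(radius):
        oa, ob = owner[a], owner[b]
        if oa == ob or _adjacent(oa, ob):
            continue
        for me, other in ((oa, ob), (ob, oa)):
            if me in in_loop:
                pos = me[1] - start
                if other in in_loop:
                    intra[pos] += 1
                else:
                    external[pos] += 1
    return list(zip(intra.tolist(), external.tolist()))


def _polar_atoms(r: Residue):
    """(donor atoms, acceptor atoms) of a residue per the chemistry table."""
    donors, acceptors = [], []
    n = r.atom("N")
    if n is not None and r.name3 != "PRO":
        donors.append(n)
    for nm in ("O", "OXT"):
        o = r.atom(nm)
        if o is not None:
            acceptors.append(o)
    for nm in _SC_DONORS.get(r.name3, ()):
        a = r.atom(nm)
        if a is not None:
            donors.append(a)
    for nm in _SC_ACCEPTORS.get(r.name3, ()):
        a = r.atom(nm)
        if a is not None:
            acceptors.append(a)
    return donors, acceptors


def detect_hbonds(s: Structure, chain_id: str, start: int, length: int,
                  radius: float = HBOND_RADIUS
                  ) -> list[tuple[int, int, int, int]]:
    """Per-position (donor_intra, donor_external, acceptor_intra,
    acceptor_external) hydrogen-bond counts for a loop window."""
    _check_window(s, chain_id, start, length)
    don_coords, don_owner = [], []
    acc_coords, acc_owner = [], []
    for cid, residues in s.chains.items():
        for idx, r in enumerate(residues):
            ds, as_ = _polar_atoms(r)
            for a in ds:
                don_coords.append(a.position)
                don_owner.append((cid, idx))
            for a in as_:
                acc_coords.append(a.position)
                acc_owner.append((cid, idx))
    in_loop = {(chain_id, i) for i in range(start, start + length)}
    di = np.zeros(length, dtype=int)
    de = np.zeros(length, dtype=int)
    ai = np.zeros(length, dtype=int)
    ae = np.zeros(length, dtype=int)
    if don_coords and acc_coords:
        don_tree = cKDTree(np.array(don_coords))
        acc_tree = cKDTree(np.array(acc_coords))
        for d_idx, neighbours in enumerate(
                don_tree.query_ball_tree(acc_tree, radius)):
            od = don_owner[d_idx]
            for a_idx in neighbours:
                oa = acc_owner[a_idx]
                if od == oa or _adjacent(od, oa):
                    continue
                if od in in_loop:
                    pos = od[1] - start
                    if oa in in_loop:
                        di[pos] += 1
                    else:
                        de[pos] += 1
                if oa in in_loop:
                    pos = oa[1] - start
                    if od in in_loop:
                        ai[pos] += 1
                    else:
                        ae[pos] += 1
    return list(zip(di.tolist(), de.tolist(), ai.tolist(), ae.tolist()))


def extract_loop_features(s: Structure, chain_id: str, start: int,
                          length: int) -> LoopInstance:
    """Bundle sequence, dihedrals and interaction counts for a loop window.

    Positions with an incomplete backbone, or whose dihedrals are undefined
    because of a chain break inside the window, are flagged rather than
    rejected.
    """
    residues = _check_window(s, chain_id, start, length)
    window = residues[start:start + length]
    dihedrals = compute_dihedrals(s)[chain_id][start:start + length]
    vdw = count_vdw_contacts(s, chain_id, start, length)
    hb = detect_hbonds(s, chain_id, start, length)
    n_chain = len(residues)
    feats: list[PositionFeatures] = []
    for i, r in enumerate(window):
        phi, psi = dihedrals[i]
        chain_pos = start + i
        missing_backbone = any(r.atom(a) is None for a in ("N", "CA", "C"))
        broken_phi = phi is None and chain_pos > 0
        broken_psi = psi is None and chain_pos + 1 < n_chain
        feats.append(PositionFeatures(
            phi=phi, psi=psi,
            vdw_intra=vdw[i][0], vdw_external=vdw[i][1],
            hbond_donor_intra=hb[i][0], hbond_donor_external=hb[i][1],
            hbond_acceptor_intra=hb[i][2], hbond_acceptor_external=hb[i][3],
            flagged=missing_backbone or broken_phi or broken_psi,
        ))
    return LoopInstance(
        structure_id=s.id, chain_id=chain_id, start=start,
        sequence="".join(r.aa1 for r in window), features=feats,
    )
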