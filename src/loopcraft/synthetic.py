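"""Synthetic structures and sequences for exercising the whole pipeline.

Three generators cover every stage without any external data:

* :func:`build_peptide` constructs an ideal-geometry backbone (N, CA, C,
  O, plus CB for non-glycine) realizing requested (phi, psi) torsions,
  with omega fixed trans.  Ideal bond lengths: N-CA 1.458 A, CA-C 1.525 A,
  C-N 1.329 A.
* :func:`generate_motif_family` plants a loop motif with a fixed sequence
  signature and a shared backbone template (plus per-position torsion
  jitter) inside randomized flanks, returning the true offsets so
  recovery can be checked.
* :func:`sample_sequences` draws profile-distributed windows embedded in
  uniform-random flanks, a stand-in database for the iterative scan.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import ALPHABET, SequenceProfile
from .structures import Atom, Residue, Structure

__all__ = [
    "MotifSpec",
    "place_atom",
    "build_peptide",
    "generate_motif_family",
    "sample_sequences",
    "HELIX_PHI_PSI",
    "STRAND_PHI_PSI",
]

# ideal backbone geometry (Engh-Huber-like); omega fixed at 180 (trans)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 120.0)

_AA1_TO_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom at `bond` A from c, with angle b-c-new and torsion
    a-b-c-new (degrees): the natural-extension construction."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  -bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_peptide(torsions: list[tuple[float, float]], sequence: str,
                  structure_id: str = "peptide",
                  chain_id: str = "A") -> Structure:
    """Ideal-geometry single-chain peptide realizing the given torsions.

    ``torsions[i]`` is (phi_i, psi_i); phi of the first residue and psi of
    the last only orient terminal atoms.  CB is placed for every non-Gly
    residue with L-amino-acid chirality.
    """
    if len(torsions) != len(sequence):
        raise ValueError("torsions and sequence must have the same length")
    n_res = len(sequence)
    if n_res == 0:
        raise ValueError("empty peptide")
    N: list[np.ndarray] = []
    CA: list[np.ndarray] = []
    C: list[np.ndarray] = []
    # first residue in a canonical frame
    N.append(np.zeros(3))
    CA.append(np.array([BOND_N_CA, 0.0, 0.0]))
    ang = np.radians(ANGLE_N_CA_C)
    C.append(CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        phi = torsions[i][0]
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1],
                            BOND_C_N, ANGLE_CA_C_N, psi_prev))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i],
                             BOND_N_CA, ANGLE_C_N_CA, OMEGA))
        C.append(place_atom(C[i - 1], N[i], CA[i],
                            BOND_CA_C, ANGLE_N_CA_C, phi))

    chain: list[Residue] = []
    for i, aa in enumerate(sequence):
        res = Residue(name3=_AA1_TO_3.get(aa, "UNK"), chain_id=chain_id,
                      seq_index=i + 1)
        res.atoms.append(Atom("N", "N", N[i]))
        res.atoms.append(Atom("CA", "C", CA[i]))
        res.atoms.append(Atom("C", "C", C[i]))
        # carbonyl O: torsion psi+180 puts it trans to the next N
        psi = torsions[i][1]
        res.atoms.append(Atom("O", "O", place_atom(
            N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)))
        if aa != "G":
            res.atoms.append(Atom("CB", "C", place_atom(
                N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB, -122.6)))
        chain.append(res)
    return Structure(id=structure_id, chains={chain_id: chain})


@dataclass
class MotifSpec:
    """Specification of a planted-motif structure family.

    ``signature`` uses one-letter codes for fixed positions and ``x`` for
    unconstrained ones; ``template`` gives per-position (phi, psi) and
    ``jitter`` the per-position torsion noise s.d. in degrees.
    """

    length: int
    signature: str
    template: list[tuple[float, float]]
    jitter: float = 5.0
    family_size: int = 30
    flank_length: int = 15
    seed: int = 0
    flank_basins: list[tuple[float, float]] = field(
        default_factory=lambda: [HELIX_PHI_PSI, STRAND_PHI_PSI, (-75.0, 150.0)])
    #: flank residues adjacent to the motif that share the motif's entry/exit
    #: conformation across the family (loops splice into conserved secondary
    #: structure; grafting anchors rely on this)
    anchor_flank: int = 4

    def __post_init__(self) -> None:
        if len(self.signature) != self.length or len(self.template) != self.length:
            raise ValueError("signature and template must match length")


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[k] for k in rng.integers(0, 20, size=n))


def generate_motif_family(spec: MotifSpec
                          ) -> tuple[list[Structure], list[int]]:
    """Family of structures each embedding the motif; returns (structures,
    true chain offsets of the motif window)."""
    rng = np.random.default_rng(spec.seed)
    structures: list[Structure] = []
    offsets: list[int] = []
    for m in range(spec.family_size):
        motif_seq = "".join(
            c if c != "x" else ALPHABET[rng.integers(0, 20)]
            for c in spec.signature)
        motif_tors = [
            (phi + rng.normal(0.0, spec.jitter),
             psi + rng.normal(0.0, spec.jitter))
            for phi, psi in spec.template]
        flank_n = spec.flank_length
        seq = (_random_sequence(rng, flank_n) + motif_seq
               + _random_sequence(rng, flank_n))
        def flank_torsion():
            basin = spec.flank_basins[rng.integers(0, len(spec.flank_basins))]
            return (basin[0] + rng.normal(0, 15.0),
                    basin[1] + rng.normal(0, 15.0))

        def anchor_torsion(basin):
            return (basin[0] + rng.normal(0.0, spec.jitter),
                    basin[1] + rng.normal(0.0, spec.jitter))

        na = min(spec.anchor_flank, flank_n)
        tors: list[tuple[float, float]] = []
        tors.extend(flank_torsion() for _ in range(flank_n - na))
        tors.extend(anchor_torsion(spec.template[0]) for _ in range(na))
        tors.extend(motif_tors)
        tors.extend(anchor_torsion(spec.template[-1]) for _ in range(na))
        tors.extend(flank_torsion() for _ in range(flank_n - na))
        structures.append(build_peptide(tors, seq,
                                        structure_id=f"fam{m:03d}"))
        offsets.append(flank_n)
    return structures, offsets


def sample_sequences(profile: SequenceProfile, n: int, flank_len: int = 20,
                     seed: int = 0) -> list[tuple[str, str]]:
    """Sequences each embedding one window drawn position-wise from the
    profile, inside uniform-random flanks."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for k in range(n):
        window = "".join(
            ALPHABET[rng.choice(20, p=profile.freqs[i] / profile.freqs[i].sum())]
            for i in range(profile.length))
        seq = (_random_sequence(rng, flank_len) + window
               + _random_sequence(rng, flank_len))
        out.append((f"seq{k:04d}", seq))
    return out
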