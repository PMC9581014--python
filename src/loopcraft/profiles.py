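"""Position-specific scoring profiles and the iterative database scan.

A loop family starts from a gapless alignment of fixed-length seed
fragments.  The alignment becomes a pseudocounted position frequency
matrix; the matrix is scanned against a sequence database in bits
(sum of per-position log2 odds against the background); segments scoring
above a threshold are pooled with the seeds and the matrix is rebuilt,
iterating until the matched-segment set stops changing.  The converged
profile is then matched against structure-derived chain sequences to
collect loop instances for descriptor assembly.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .features import LoopInstance, extract_loop_features
from .structures import Structure

__all__ = [
    "ALPHABET",
    "SequenceProfile",
    "ProfileMatch",
    "read_fasta",
    "write_fasta",
    "build_pssm",
    "scan_database",
    "iterate_profile",
    "match_structures",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def read_fasta(source) -> list[tuple[str, str]]:
    """Read FASTA from a path or file-like object as (id, sequence) pairs."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(source, "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


@dataclass
class SequenceProfile:
    """N x 20 per-position amino-acid frequencies with background model."""

    freqs: np.ndarray          # (N, 20), rows sum to 1
    background: np.ndarray     # (20,)
    pseudocount: float
    n_sequences: int
    provenance: list[str] = field(default_factory=list)
    flag: str = ""             # e.g. "unconverged-empty"
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(N, 20) log2(w / background); letters outside the alphabet score 0."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.freqs / self.background[None, :])
        lo[~np.isfinite(lo)] = -np.inf
        return lo


@dataclass(frozen=True)
class ProfileMatch:
    sequence_id: str
    offset: int
    score: float  # bits


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=int)


def build_pssm(alignment: list[str] | list[tuple[str, str]],
               pseudocount: float = 1.0,
               background: np.ndarray | None = None) -> SequenceProfile:
    """Position frequency matrix from a gapless, equal-length alignment.

    freqs = (counts + pseudocount * background) / (n + pseudocount).
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    n = len(seqs[0])
    for s in seqs:
        if len(s) != n:
            raise ValueError("alignment sequences must all have equal length")
        if "-" in s or "." in s:
            raise ValueError("alignment must be gapless")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    counts = np.zeros((n, 20))
    for s in seqs:
        for i, c in enumerate(s):
            k = _AA_INDEX.get(c)
            if k is not None:
                counts[i, k] += 1
    freqs = (counts + pseudocount * np.asarray(background)[None, :]) / (
        counts.sum(axis=1, keepdims=True) + pseudocount)
    return SequenceProfile(freqs=freqs, background=np.asarray(background),
                           pseudocount=pseudocount, n_sequences=len(seqs))


def score_windows(profile: SequenceProfile, seq: str) -> np.ndarray:
    """Bit score of every length-N window of `seq` (empty if too short)."""
    n = profile.length
    enc = _encode(seq)
    if len(enc) < n:
        return np.zeros(0)
    lo = profile.log_odds()
    # per-position score rows; unknown letters contribute 0 bits
    per_pos = np.zeros((len(enc), n))
    valid = enc >= 0
    for j in range(n):
        per_pos[valid, j] = lo[j, enc[valid]]
    n_win = len(enc) - n + 1
    scores = np.empty(n_win)
    for w in range(n_win):
        scores[w] = per_pos[np.arange(w, w + n), np.arange(n)].sum()
    return scores


def _best_nonoverlapping(scores: np.ndarray, n: int,
                         threshold: float) -> list[tuple[int, float]]:
    """Greedy best-score-first selection of non-overlapping windows;
    ties break toward the smaller offset."""
    order = sorted(range(len(scores)), key=lambda w: (-scores[w], w))
    taken: list[tuple[int, float]] = []
    occupied = np.zeros(len(scores) + n, dtype=bool)
    for w in order:
        if scores[w] < threshold:
            break
        if occupied[w:w + n].any():
            continue
        occupied[w:w + n] = True
        taken.append((w, float(scores[w])))
    taken.sort()
    return taken


def scan_database(profile: SequenceProfile,
                  db: list[tuple[str, str]],
                  threshold: float) -> list[ProfileMatch]:
    """All above-threshold, non-overlapping profile windows in a database."""
    matches: list[ProfileMatch] = []
    for sid, seq in db:
        scores = score_windows(profile, seq)
        if scores.size == 0:
            continue
        for offset, score in _best_nonoverlapping(scores, profile.length,
                                                  threshold):
            matches.append(ProfileMatch(sid, offset, score))
    return matches


def iterate_profile(seeds: list[str] | list[tuple[str, str]],
                    db: list[tuple[str, str]],
                    threshold: float,
                    max_iter: int = 20,
                    tol: float = 1e-9,
                    pseudocount: float = 1.0,
                    background: np.ndarray | None = None) -> SequenceProfile:
    """Expand a seed profile against a database until it stops changing.

    Each round scans the database with the current profile, pools the seed
    fragments with every matched segment, and rebuilds the frequency
    matrix.  Convergence: identical matched-segment set, or max-norm
    frequency change below `tol`, or `max_iter` rounds.  If the very first
    scan yields nothing the seed profile is returned flagged
    ``unconverged-empty``.
    """
    seed_seqs = [s[1] if isinstance(s, tuple) else s for s in seeds]
    profile = build_pssm(seed_seqs, pseudocount=pseudocount,
                         background=background)
    n = profile.length
    db_index = dict(db)
    prev_set: set[tuple[str, int]] | None = None
    matches: list[ProfileMatch] = []
    n_iter = 0
    for _ in range(max_iter):
        matches = scan_database(profile, db, threshold)
        match_set = {(m.sequence_id, m.offset) for m in matches}
        if prev_set is None and not match_set:
            profile.flag = "unconverged-empty"
            return profile
        segments = [db_index[m.sequence_id][m.offset:m.offset + n]
                    for m in matches]
        # pool matched segments with the seeds; a matched segment identical
        # to a seed consumes it, so seeds present in the database are not
        # counted twice and a database equal to the seeds is a fixed point
        remaining = Counter(segments)
        pool = list(segments)
        for s in seed_seqs:
            if remaining[s] > 0:
                remaining[s] -= 1
            else:
                pool.append(s)
        new_profile = build_pssm(pool, pseudocount=pseudocount,
                                 background=background)
        delta = float(np.abs(new_profile.freqs - profile.freqs).max())
        converged = match_set == prev_set or delta < tol
        profile = new_profile
        prev_set = match_set
        n_iter += 1
        if converged:
            break
    profile.provenance = [f"{m.sequence_id}:{m.offset}" for m in matches]
    profile.n_iterations = n_iter
    return profile


def match_structures(profile: SequenceProfile,
                     structures: list[Structure],
                     threshold: float) -> list[LoopInstance]:
    """Scan chain sequences of structures; extract features of each match."""
    instances: list[LoopInstance] = []
    for s in structures:
        for chain_id, residues in s.chains.items():
            seq = "".join(r.aa1 for r in residues)
            scores = score_windows(profile, seq)
            if scores.size == 0:
                continue
            for offset, _score in _best_nonoverlapping(
                    scores, profile.length, threshold):
                instances.append(
                    extract_loop_features(s, chain_id, offset, profile.length))
    return instances
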