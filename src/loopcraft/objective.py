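"""The weighted multi-feature objective function.

A candidate loop is scored against a descriptor as

    F = sum_i sum_j  W_i^P  W_ij^F  S_ij

over N positions and the features j in {a (sequence), d (dihedrals),
v (VdW contacts), hA (H-bond acceptors), hD (H-bond donors)}.  All
similarity scores S_ij live in [0, 1]:

* sequence: the profile-frequency-weighted expected BLOSUM62 log-odds of
  the query residue, min-max rescaled by the matrix's global range;
* dihedrals: S = 1 - erf(sum_k pi_k D_k^T Lambda_k D_k) with D the
  wrap-aware displacement from each mixture component mean, normalized
  per dimension by the descriptor's median spread;
* counts: S = 1 - |x - y| / max(x, y), i.e. one minus the relative
  count mismatch, with S = 1 when both counts are zero.

Undefined features (chain breaks in the query, no-data descriptor
positions, unknown residues) score a neutral 0.5 so that missing data
neither rewards nor penalizes a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf
from Bio.Align import substitution_matrices

from .descriptor import (Descriptor, DescriptorPosition, DihedralClusterModel,
                         wrap_diff)
from .features import LoopInstance, PositionFeatures, extract_loop_features
from .profiles import ALPHABET

__all__ = [
    "FEATURES",
    "NEUTRAL_SCORE",
    "ScoreBreakdown",
    "blosum62_entry",
    "score_sequence",
    "score_sequence_pair",
    "score_dihedral",
    "score_dihedral_pair",
    "score_counts",
    "score_position",
    "score_position_pair",
    "score_loop",
    "score_all_windows",
]

FEATURES = ("a", "d", "v", "hA", "hD")
NEUTRAL_SCORE = 0.5

_B62 = substitution_matrices.load("BLOSUM62")
_B62_LOOKUP = {(a, b): float(_B62[a, b]) for a in ALPHABET for b in ALPHABET}
_B62_MIN = min(_B62_LOOKUP.values())
_B62_MAX = max(_B62_LOOKUP.values())


def blosum62_entry(a: str, b: str) -> float:
    """Raw BLOSUM62 log-odds entry for two standard residues."""
    return _B62_LOOKUP[(a, b)]


def _rescale_b62(v: float) -> float:
    return (v - _B62_MIN) / (_B62_MAX - _B62_MIN)


def score_sequence(aa: str, pos: DescriptorPosition,
                   mode: str = "expected") -> float:
    """Sequence similarity S_i,a of a query residue to a profile column.

    ``expected``: frequency-weighted expected BLOSUM62 score; ``consensus``:
    BLOSUM62 score against the most frequent residue.  Both are rescaled to
    [0, 1] by the matrix's global min/max.  'X' scores neutral.
    """
    if aa not in _AA_SET:
        return NEUTRAL_SCORE
    if mode == "consensus":
        consensus = ALPHABET[int(np.argmax(pos.aa_freqs))]
        return _rescale_b62(_B62_LOOKUP[(aa, consensus)])
    if mode != "expected":
        raise ValueError(f"unknown sequence scoring mode {mode!r}")
    row = np.array([_B62_LOOKUP[(aa, b)] for b in ALPHABET])
    return _rescale_b62(float(row @ pos.aa_freqs))


_AA_SET = set(ALPHABET)


def score_sequence_pair(aa_x: str, aa_y: str) -> float:
    """Pairwise residue similarity: rescaled BLOSUM62(aa_x, aa_y)."""
    if aa_x not in _AA_SET or aa_y not in _AA_SET:
        return NEUTRAL_SCORE
    return _rescale_b62(_B62_LOOKUP[(aa_x, aa_y)])


def score_dihedral(point: tuple[float | None, float | None],
                   model: DihedralClusterModel) -> float:
    """S_i,d = 1 - erf(sum_k pi_k D_k^T Lambda_k D_k).

    D_k is the wrap-aware displacement of the query (phi, psi) from
    component k's mean, normalized per dimension by the stored median
    spread.  At a component mean of a one-component model S = 1; the score
    decays monotonically with distance.  Undefined points and no-data
    models score neutral.
    """
    if model.no_data or point[0] is None or point[1] is None:
        return NEUTRAL_SCORE
    x = np.asarray(point, dtype=float)
    d = wrap_diff(x[None, :], model.means) / model.median_norm[None, :]
    q = float(np.sum(model.weights[:, None] * model.precisions * d ** 2))
    return float(1.0 - erf(q))


def score_dihedral_pair(x: tuple[float | None, float | None],
                        y: tuple[float | None, float | None],
                        model: DihedralClusterModel) -> float:
    """Pairwise dihedral similarity of two (phi, psi) points under the
    position's total precision C = sum_k pi_k Lambda_k."""
    if (model.no_data or x[0] is None or x[1] is None
            or y[0] is None or y[1] is None):
        return NEUTRAL_SCORE
    d = wrap_diff(np.asarray(x, float), np.asarray(y, float)) / model.median_norm
    c = np.sum(model.weights[:, None] * model.precisions, axis=0)
    q = float(np.sum(c * np.asarray(d) ** 2))
    return float(1.0 - erf(q))


def score_counts(x: int | float, y: int | float) -> float:
    """1 minus the relative count mismatch |x-y|/max(x,y); equal counts
    (including both zero) score 1."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    m = max(x, y)
    if m == 0:
        return 1.0
    return 1.0 - abs(x - y) / m


def _loop_counts(f: PositionFeatures) -> dict[str, int]:
    return {"v": f.vdw_total, "hA": f.hbond_acceptor_total,
            "hD": f.hbond_donor_total}


_COUNT_KEY = {"v": "vdw", "hA": "hbond_acceptor", "hD": "hbond_donor"}


def score_position(aa: str, f: PositionFeatures, pos: DescriptorPosition,
                   sequence_mode: str = "expected") -> dict[str, float]:
    """All five S_ij of one loop position against one descriptor position."""
    if f.flagged or pos.no_data:
        return {j: NEUTRAL_SCORE for j in FEATURES}
    s = {"a": score_sequence(aa, pos, mode=sequence_mode),
         "d": score_dihedral((f.phi, f.psi), pos.dihedral_model)}
    counts = _loop_counts(f)
    for j in ("v", "hA", "hD"):
        s[j] = score_counts(counts[j], pos.count_dists[_COUNT_KEY[j]].reference)
    return s


def score_position_pair(aa_x: str, fx: PositionFeatures,
                        aa_y: str, fy: PositionFeatures,
                        pos: DescriptorPosition) -> dict[str, float]:
    """Pairwise S_ij between two realizations of one descriptor position.

    Used when ranking provenance sources against a target scaffold: the
    descriptor supplies the weights and the dihedral precision scale, the
    two loops supply the compared values.
    """
    if fx.flagged or fy.flagged:
        return {j: NEUTRAL_SCORE for j in FEATURES}
    s = {"a": score_sequence_pair(aa_x, aa_y),
         "d": score_dihedral_pair((fx.phi, fx.psi), (fy.phi, fy.psi),
                                  pos.dihedral_model)}
    cx, cy = _loop_counts(fx), _loop_counts(fy)
    for j in ("v", "hA", "hD"):
        s[j] = score_counts(cx[j], cy[j])
    return s


@dataclass
class ScoreBreakdown:
    """Per-position, per-feature scores with weights and the total F."""

    scores: np.ndarray           # (N, 5) S_ij, feature order FEATURES
    feature_weights: np.ndarray  # (N, 5) W_ij^F
    position_weights: np.ndarray  # (N,) W_i^P
    total: float

    def position_contribution(self, i: int) -> float:
        return float(self.position_weights[i]
                     * (self.feature_weights[i] @ self.scores[i]))

    def to_tsv(self) -> str:
        lines = ["position\tfeature\tscore\tfeature_weight\t"
                 "position_weight\tcontribution"]
        n = self.scores.shape[0]
        for i in range(n):
            for j, tag in enumerate(FEATURES):
                contrib = (self.position_weights[i]
                           * self.feature_weights[i, j] * self.scores[i, j])
                lines.append(f"{i}\t{tag}\t{self.scores[i, j]:.6f}\t"
                             f"{self.feature_weights[i, j]:.6f}\t"
                             f"{self.position_weights[i]:.6f}\t{contrib:.6g}")
        lines.append(f"total\tF\t{self.total:.6g}\t\t\t")
        return "\n".join(lines) + "\n"


def score_loop(loop: LoopInstance, d: Descriptor,
               sequence_mode: str = "expected") -> ScoreBreakdown:
    """Score a loop instance against a descriptor; returns the breakdown."""
    if loop.length != d.length:
        raise ValueError(
            f"loop length {loop.length} != descriptor length {d.length}")
    n = d.length
    scores = np.zeros((n, len(FEATURES)))
    weights = np.zeros((n, len(FEATURES)))
    pos_w = np.array([p.position_weight for p in d.positions])
    for i, pos in enumerate(d.positions):
        s = score_position(loop.sequence[i], loop.features[i], pos,
                           sequence_mode=sequence_mode)
        fw = pos.feature_weights()
        for j, tag in enumerate(FEATURES):
            scores[i, j] = s[tag]
            weights[i, j] = fw[tag]
    total = float(np.sum(pos_w[:, None] * weights * scores))
    return ScoreBreakdown(scores=scores, feature_weights=weights,
                          position_weights=pos_w, total=total)


def score_all_windows(s, chain_id: str, d: Descriptor,
                      sequence_mode: str = "expected") -> np.ndarray:
    """F for every window of a chain (empty array if the chain is shorter
    than the descriptor).

    Interaction totals per residue do not depend on the window placement,
    so features are extracted once for the whole chain and sliced.
    """
    residues = s.chain(chain_id)
    n = d.length
    if len(residues) < n:
        return np.zeros(0)
    whole = extract_loop_features(s, chain_id, 0, len(residues))
    out = np.empty(len(residues) - n + 1)
    for w in range(len(out)):
        window = LoopInstance(
            structure_id=s.id, chain_id=chain_id, start=w,
            sequence=whole.sequence[w:w + n],
            features=whole.features[w:w + n])
        out[w] = score_loop(window, d, sequence_mode=sequence_mode).total
    return out
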