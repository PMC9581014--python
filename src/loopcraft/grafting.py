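"""Finding and placing the best realization of a descriptor in a scaffold.

The search works on a (source x position) score matrix: every provenance
loop of the descriptor is compared position-wise against the target window
(pairwise sequence/dihedral/contact similarity under the descriptor's
weights).  A seven-residue seed segment with the highest cumulative score
is located, then extended greedily one position at a time from either end,
switching to another source only where that source scores strictly higher
(plus an optional hysteresis margin).  The result is a graft plan — an
ordered set of non-overlapping segments jointly covering the loop — whose
backbone coordinates are transplanted into the target by least-squares
superposition on three flanking anchor residues per side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .descriptor import Descriptor
from .features import LoopInstance, extract_loop_features
from .objective import FEATURES, score_position_pair
from .structures import Structure, Residue

__all__ = [
    "SEED_LENGTH",
    "SegmentMatch",
    "GraftPlan",
    "GraftReport",
    "score_position_matrix",
    "find_seed_segment",
    "extend_and_merge",
    "plan_graft",
    "graft_loop",
    "kabsch",
]

SEED_LENGTH = 7
CLASH_DISTANCE = 2.0  # A, heavy-atom clash threshold in the report


@dataclass
class SegmentMatch:
    source_id: str          # provenance LoopInstance id
    start: int              # first descriptor position covered (inclusive)
    end: int                # one past the last position covered
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GraftPlan:
    target_chain: str
    target_start: int
    segments: list[SegmentMatch]
    total_score: float

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start != prev_end:
                raise ValueError("segments must tile positions without gaps")
            prev_end = seg.end

    @property
    def length(self) -> int:
        return self.segments[-1].end if self.segments else 0

    def source_per_position(self) -> list[str]:
        out = []
        for seg in self.segments:
            out.extend([seg.source_id] * seg.length)
        return out


@dataclass
class GraftReport:
    plan: GraftPlan
    junction_ca_ca: list[float]   # adjacent C-alpha distances across junctions
    junction_c_n: list[float]     # peptide C-N distances across junctions
    clash_count: int

    def to_tsv(self) -> str:
        lines = ["record\tvalue"]
        for seg in self.plan.segments:
            lines.append(f"segment\t{seg.source_id}:{seg.start}-{seg.end}"
                         f" score={seg.score:.6g}")
        for k, (ca, cn) in enumerate(zip(self.junction_ca_ca,
                                         self.junction_c_n)):
            lines.append(f"junction_{k}_ca_ca\t{ca:.3f}")
            lines.append(f"junction_{k}_c_n\t{cn:.3f}")
        lines.append(f"clash_count\t{self.clash_count}")
        lines.append(f"total_score\t{self.plan.total_score:.6g}")
        return "\n".join(lines) + "\n"


def score_position_matrix(target: Structure, chain_id: str, start: int,
                          d: Descriptor) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-source, per-position weighted fit scores against a target window.

    Returns ``(matrix, valid, source_ids)`` where ``matrix[s, i]`` is
    W_i^P * sum_j W_ij^F * S_ij between provenance source s and the target
    at descriptor position i, ``valid[i]`` is False where the target
    position is unresolved (those entries are NaN), and ``source_ids``
    orders the rows.
    """
    if not d.provenance:
        raise ValueError("descriptor carries no provenance loop instances")
    target_loop = extract_loop_features(target, chain_id, start, d.length)
    valid = np.array([not f.flagged for f in target_loop.features])
    sources = sorted(d.provenance, key=lambda inst: inst.source_id)
    matrix = np.full((len(sources), d.length), np.nan)
    for si, src in enumerate(sources):
        for i, pos in enumerate(d.positions):
            if not valid[i]:
                continue
            s = score_position_pair(src.sequence[i], src.features[i],
                                    target_loop.sequence[i],
                                    target_loop.features[i], pos)
            fw = pos.feature_weights()
            matrix[si, i] = pos.position_weight * sum(
                fw[tag] * s[tag] for tag in FEATURES)
    return matrix, valid, [inst.source_id for inst in sources]


def find_seed_segment(matrix: np.ndarray, valid: np.ndarray,
                      source_ids: list[str],
                      seed_length: int = SEED_LENGTH) -> SegmentMatch:
    """Best `seed_length`-window over all (source, start) pairs.

    Ties break toward the smaller start, then the lexicographically
    smaller source id.  Raises if no run of `seed_length` valid positions
    exists.
    """
    n = matrix.shape[1]
    best: SegmentMatch | None = None
    order = sorted(range(len(source_ids)), key=lambda s: source_ids[s])
    for w in range(n - seed_length + 1):
        if not valid[w:w + seed_length].all():
            continue
        for s in order:
            total = float(matrix[s, w:w + seed_length].sum())
            if best is None or total > best.score:
                best = SegmentMatch(source_ids[s], w, w + seed_length, total)
    if best is None:
        raise ValueError("no valid seed: no run of "
                         f"{seed_length} resolved positions")
    return best


def extend_and_merge(seed: SegmentMatch, matrix: np.ndarray,
                     valid: np.ndarray, source_ids: list[str],
                     switch_margin: float = 0.0) -> GraftPlan:
    """Grow the seed to full descriptor coverage, switching sources greedily.

    At each step the uncovered position adjacent to either end is examined;
    the end whose best attainable score is higher is extended first.  The
    current end's source is kept unless another source scores higher by
    more than `switch_margin`.  Unresolved positions carry the current
    source through with zero score contribution.
    """
    n = matrix.shape[1]
    idx = {sid: k for k, sid in enumerate(source_ids)}
    chosen = [None] * n  # source id per position
    for i in range(seed.start, seed.end):
        chosen[i] = seed.source_id
    lo, hi = seed.start, seed.end
    total = seed.score

    def candidate(pos: int, current: str) -> tuple[str, float]:
        if not valid[pos]:
            return current, 0.0
        cur_score = matrix[idx[current], pos]
        col = matrix[:, pos]
        best_s = int(np.nanargmax(col))
        # deterministic tie-break toward the lexicographically smaller id
        best_val = col[best_s]
        ties = [k for k in range(len(col)) if col[k] == best_val]
        best_s = min(ties, key=lambda k: source_ids[k])
        if best_val > cur_score + switch_margin:
            return source_ids[best_s], float(best_val)
        return current, float(cur_score)

    while lo > 0 or hi < n:
        left = candidate(lo - 1, chosen[lo]) if lo > 0 else None
        right = candidate(hi, chosen[hi - 1]) if hi < n else None
        go_left = right is None or (left is not None
                                    and left[1] > right[1])
        if go_left:
            lo -= 1
            chosen[lo], gain = left
        else:
            chosen[hi], gain = right
            hi += 1
        total += gain

    segments: list[SegmentMatch] = []
    seg_start = 0
    for i in range(1, n + 1):
        if i == n or chosen[i] != chosen[seg_start]:
            seg_score = float(np.nansum(
                matrix[idx[chosen[seg_start]], seg_start:i]
                [valid[seg_start:i]]))
            segments.append(SegmentMatch(chosen[seg_start], seg_start, i,
                                         seg_score))
            seg_start = i
    return GraftPlan(target_chain="", target_start=0, segments=segments,
                     total_score=float(total))


def plan_graft(target: Structure, chain_id: str, start: int, d: Descriptor,
               seed_length: int = SEED_LENGTH,
               switch_margin: float = 0.0) -> GraftPlan:
    """Score, seed and extend in one call; returns a complete GraftPlan."""
    matrix, valid, source_ids = score_position_matrix(target, chain_id,
                                                      start, d)
    seed = find_seed_segment(matrix, valid, source_ids,
                             seed_length=seed_length)
    plan = extend_and_merge(seed, matrix, valid, source_ids,
                            switch_margin=switch_margin)
    plan.target_chain = chain_id
    plan.target_start = start
    return plan


def kabsch(mobile: np.ndarray, fixed: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superposition: returns (rotation, mobile_centroid,
    fixed_centroid) so that (x - mc) @ R.T + fc aligns mobile onto fixed."""
    mc = mobile.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (mobile - mc).T @ (fixed - fc)
    u, _s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    dd = np.diag([1.0, 1.0, sign])
    rot = vt.T @ dd @ u.T
    return rot, mc, fc


def _backbone_coords(residues: list[Residue], what=("N", "CA", "C")
                     ) -> np.ndarray:
    coords = []
    for r in residues:
        for name in what:
            a = r.atom(name)
            if a is None:
                raise ValueError(
                    f"missing backbone atom {name} in residue "
                    f"{r.chain_id}{r.seq_index}")
            coords.append(a.position)
    return np.array(coords)


def graft_loop(target: Structure, chain_id: str, start: int,
               plan: GraftPlan, d: Descriptor,
               library: dict[str, Structure],
               n_anchor: int = 3) -> tuple[Structure, GraftReport]:
    """Transplant the planned segments into the target scaffold.

    Each segment's source backbone is superposed onto the original target
    coordinates of the `n_anchor` residues flanking the segment on each
    side (scaffold flanks at the window edges, in-window junction residues
    at internal boundaries); the target residues are then replaced by the
    transformed source residues, keeping the target's chain id and author
    numbering.  Side chains come from the source unchanged.
    """
    n = plan.length
    target_res = target.chain(chain_id)
    if start < n_anchor or start + n + n_anchor > len(target_res):
        raise ValueError(
            f"target window must be flanked by >= {n_anchor} resolved "
            "residues on each side")
    by_source = {inst.source_id: inst for inst in d.provenance}
    result = target.copy()
    new_chain = result.chain(chain_id)

    for seg in plan.segments:
        inst = by_source.get(seg.source_id)
        if inst is None:
            raise KeyError(f"plan references unknown source {seg.source_id!r}")
        src_structure = library.get(inst.structure_id)
        if src_structure is None:
            raise KeyError(
                f"provenance structure {inst.structure_id!r} not in library")
        src_res = src_structure.chain(inst.chain_id)
        src_lo = inst.start + seg.start
        src_hi = inst.start + seg.end
        # anchors: n_anchor residues flanking the segment on each side,
        # taken from the ORIGINAL target coordinates
        t_lo = start + seg.start
        t_hi = start + seg.end
        t_anchors = (target_res[t_lo - n_anchor:t_lo]
                     + target_res[t_hi:t_hi + n_anchor])
        s_anchors = (src_res[src_lo - n_anchor:src_lo]
                     + src_res[src_hi:src_hi + n_anchor])
        if (len(t_anchors) != 2 * n_anchor or len(s_anchors) != 2 * n_anchor):
            raise ValueError(
                f"missing anchor residues for segment {seg.source_id}"
                f":{seg.start}-{seg.end}")
        rot, mc, fc = kabsch(_backbone_coords(s_anchors),
                             _backbone_coords(t_anchors))
        for k, src_r in enumerate(src_res[src_lo:src_hi]):
            tgt_r = new_chain[t_lo + k]
            tgt_r.name3 = src_r.name3
            tgt_r.atoms = [
                type(a)(name=a.name, element=a.element,
                        position=(a.position - mc) @ rot.T + fc,
                        occupancy=a.occupancy)
                for a in src_r.atoms]

    report = _graft_report(result, chain_id, start, plan)
    return result, report


def _graft_report(result: Structure, chain_id: str, start: int,
                  plan: GraftPlan) -> GraftReport:
    chain = result.chain(chain_id)
    n = plan.length
    # junctions: window entry, internal segment boundaries, window exit
    boundaries = [start]
    for seg in plan.segments[1:]:
        boundaries.append(start + seg.start)
    boundaries.append(start + n)
    ca_ca, c_n = [], []
    for b in boundaries:
        prev_r, next_r = chain[b - 1], chain[b]
        ca1, ca2 = prev_r.atom("CA"), next_r.atom("CA")
        c, nn = prev_r.atom("C"), next_r.atom("N")
        ca_ca.append(float(np.linalg.norm(ca1.position - ca2.position))
                     if ca1 and ca2 else float("nan"))
        c_n.append(float(np.linalg.norm(c.position - nn.position))
                   if c and nn else float("nan"))

    # clash count: grafted heavy atoms too close to retained scaffold atoms,
    # sequence-adjacent residue pairs excluded (junction bonds are covalent)
    grafted = set(range(start, start + n))
    g_coords, g_idx, s_coords, s_idx = [], [], [], []
    for cid, residues in result.chains.items():
        for i, r in enumerate(residues):
            for a in r.atoms:
                if a.is_hydrogen:
                    continue
                if cid == chain_id and i in grafted:
                    g_coords.append(a.position)
                    g_idx.append((cid, i))
                else:
                    s_coords.append(a.position)
                    s_idx.append((cid, i))
    clash = 0
    if g_coords and s_coords:
        tree = cKDTree(np.array(s_coords))
        for gi, neighbours in enumerate(
                tree.query_ball_point(np.array(g_coords), CLASH_DISTANCE)):
            for si in neighbours:
                same_chain = g_idx[gi][0] == s_idx[si][0]
                if same_chain and abs(g_idx[gi][1] - s_idx[si][1]) <= 1:
                    continue
                clash += 1
    return GraftReport(plan=plan, junction_ca_ca=ca_ca, junction_c_n=c_n,
                       clash_count=clash)
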