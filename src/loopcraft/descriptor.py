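"""Descriptor assembly: the per-position statistical bundle of a loop family.

For each of the N loop positions the descriptor stores

* amino-acid frequencies pooled over the contributing loop instances,
* a diagonal Gaussian mixture over wrap-adjusted (phi, psi) dihedrals,
  with the component count chosen by BIC,
* half-normal spread parameters of the VdW-contact and H-bond counts,
* per-feature weights W_ij^F and the normalized per-position weight W_i^P.

The sequence feature weight is the summed frequency of the two most common
residues; the weights of the structural features are the half-normal sigma
of each feature's spread, each multiplied by a configurable scalar factor.
W_i^P = sum_j W_ij^F / sum_i sum_j W_ij^F, so position weights sum to one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .features import LoopInstance
from .profiles import ALPHABET

__all__ = [
    "SCHEMA_VERSION",
    "DihedralClusterModel",
    "CountDistribution",
    "DescriptorPosition",
    "Descriptor",
    "wrap_angle",
    "wrap_diff",
    "circular_mean",
    "cluster_dihedrals",
    "fit_halfnormal_sigma",
    "compute_seq_weight",
    "assemble_descriptor",
    "save_descriptor",
    "load_descriptor",
]

SCHEMA_VERSION = 1

VARIANCE_FLOOR = 1.0      # deg^2, precision cap on conserved positions
MEDIAN_FLOOR = 1.0        # deg, displacement normalizer floor
COUNT_FEATURES = ("vdw", "hbond_donor", "hbond_acceptor")


def wrap_angle(a: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def wrap_diff(a, b):
    """Wrap-aware difference a - b in degrees, elementwise, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(d == -180.0, 180.0, d)


def circular_mean(angles: np.ndarray) -> float:
    """Mean direction of angles in degrees."""
    rad = np.radians(np.asarray(angles, dtype=float))
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


@dataclass
class DihedralClusterModel:
    """Diagonal Gaussian mixture over (phi, psi), wrap-adjusted.

    `means` are in (-180, 180]; `variances` are floored; `posteriors` is
    the responsibility matrix of the training points; `median_norm` holds
    the per-dimension median absolute wrap deviation from the circular
    mean, used to normalize displacements at scoring time.
    """

    means: np.ndarray            # (K, 2) degrees
    variances: np.ndarray        # (K, 2) deg^2, >= VARIANCE_FLOOR
    weights: np.ndarray          # (K,), sums to 1
    posteriors: np.ndarray       # (n_points, K)
    median_norm: np.ndarray      # (2,) degrees, >= MEDIAN_FLOOR
    no_data: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        self.median_norm = np.asarray(self.median_norm, dtype=float)

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def precisions(self) -> np.ndarray:
        """Lambda = sigma^-2 per component and dimension."""
        return 1.0 / self.variances

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "weights": self.weights.tolist(),
            "posteriors": self.posteriors.tolist(),
            "median_norm": self.median_norm.tolist(),
            "no_data": self.no_data,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DihedralClusterModel":
        return cls(means=np.array(d["means"]), variances=np.array(d["variances"]),
                   weights=np.array(d["weights"]),
                   posteriors=np.array(d["posteriors"]),
                   median_norm=np.array(d["median_norm"]),
                   no_data=d["no_data"])

    @classmethod
    def empty(cls) -> "DihedralClusterModel":
        return cls(means=np.zeros((1, 2)),
                   variances=np.full((1, 2), VARIANCE_FLOOR),
                   weights=np.ones(1), posteriors=np.zeros((0, 1)),
                   median_norm=np.full(2, MEDIAN_FLOOR), no_data=True)


def cluster_dihedrals(points: list[tuple[float, float]], max_K: int = 3,
                      seed: int = 0) -> DihedralClusterModel:
    """EM clustering of (phi, psi) points with BIC model selection.

    Angles are unwrapped around their circular mean before fitting so that
    clusters straddling the +/-180 degree seam stay together.  Deterministic
    for a given seed.
    """
    pts = np.array([p for p in points
                    if p[0] is not None and p[1] is not None], dtype=float)
    if pts.size == 0:
        return DihedralClusterModel.empty()
    # sort points so the fit (k-means init) is order-invariant
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    centers = np.array([circular_mean(pts[:, 0]), circular_mean(pts[:, 1])])
    unwrapped = centers[None, :] + wrap_diff(pts, centers[None, :])
    median_norm = np.maximum(
        np.median(np.abs(unwrapped - centers[None, :]), axis=0), MEDIAN_FLOOR)

    best = None
    best_bic = np.inf
    for k in range(1, min(max_K, len(pts)) + 1):
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             reg_covar=VARIANCE_FLOOR, random_state=seed,
                             n_init=1, max_iter=300)
        with warnings.catch_warnings():
            # duplicate points at conserved positions collapse clusters;
            # that is expected, not a fitting failure
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(unwrapped)
        bic = gm.bic(unwrapped)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    means = np.array([[wrap_angle(m[0]), wrap_angle(m[1])] for m in best.means_])
    variances = np.maximum(best.covariances_, VARIANCE_FLOOR)
    return DihedralClusterModel(
        means=means, variances=variances, weights=best.weights_,
        posteriors=best.predict_proba(unwrapped), median_norm=median_norm)


def fit_halfnormal_sigma(values) -> float:
    """Half-normal maximum-likelihood scale: sigma = sqrt(mean(x^2))."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if np.any(x < 0):
        raise ValueError("half-normal values must be non-negative")
    return float(np.sqrt(np.mean(x ** 2)))


def compute_seq_weight(aa_freqs) -> float:
    """Summed relative frequency of the two most frequent residues."""
    f = np.asarray(aa_freqs, dtype=float)
    top2 = np.sort(f)[-2:].sum()
    return float(top2 / f.sum())


@dataclass
class CountDistribution:
    feature: str              # one of COUNT_FEATURES
    counts: list[int]         # pooled intra+external totals, one per instance
    intra_mean: float
    external_mean: float
    sigma: float              # half-normal scale of the counts' spread

    @property
    def reference(self) -> int:
        """Rounded mean total count, the comparison target at scoring time."""
        return int(round(float(np.mean(self.counts)))) if self.counts else 0

    def to_dict(self) -> dict:
        return {"feature": self.feature, "counts": list(self.counts),
                "intra_mean": self.intra_mean,
                "external_mean": self.external_mean, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "CountDistribution":
        return cls(**d)


@dataclass
class DescriptorPosition:
    aa_freqs: np.ndarray                 # (20,)
    weight_seq: float                    # W_i,a^F
    dihedral_model: DihedralClusterModel
    weight_dihedral: float               # W_i,d^F
    count_dists: dict[str, CountDistribution]
    count_weights: dict[str, float]      # W_i,v^F, W_i,hA^F, W_i,hD^F
    position_weight: float = 0.0         # W_i^P, normalized over positions
    no_data: bool = False

    def __post_init__(self) -> None:
        self.aa_freqs = np.asarray(self.aa_freqs, dtype=float)

    def feature_weights(self) -> dict[str, float]:
        return {"a": self.weight_seq, "d": self.weight_dihedral,
                "v": self.count_weights["vdw"],
                "hA": self.count_weights["hbond_acceptor"],
                "hD": self.count_weights["hbond_donor"]}

    def to_dict(self) -> dict:
        return {
            "aa_freqs": self.aa_freqs.tolist(),
            "weight_seq": self.weight_seq,
            "dihedral_model": self.dihedral_model.to_dict(),
            "weight_dihedral": self.weight_dihedral,
            "count_dists": {k: v.to_dict() for k, v in self.count_dists.items()},
            "count_weights": dict(self.count_weights),
            "position_weight": self.position_weight,
            "no_data": self.no_data,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorPosition":
        return cls(
            aa_freqs=np.array(d["aa_freqs"]), weight_seq=d["weight_seq"],
            dihedral_model=DihedralClusterModel.from_dict(d["dihedral_model"]),
            weight_dihedral=d["weight_dihedral"],
            count_dists={k: CountDistribution.from_dict(v)
                         for k, v in d["count_dists"].items()},
            count_weights=dict(d["count_weights"]),
            position_weight=d["position_weight"], no_data=d["no_data"],
        )


@dataclass
class Descriptor:
    name: str
    length: int
    positions: list[DescriptorPosition]
    scale_factors: dict[str, float] = field(
        default_factory=lambda: {"d": 1.0, "v": 1.0, "hA": 1.0, "hD": 1.0})
    provenance: list[LoopInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.positions) != self.length:
            raise ValueError("positions list must match descriptor length")

    def logo_table(self) -> str:
        """Per-position amino-acid frequencies as TSV (for logo plotting)."""
        lines = ["position\t" + "\t".join(ALPHABET)]
        for i, p in enumerate(self.positions):
            lines.append(str(i) + "\t" +
                         "\t".join(f"{f:.6f}" for f in p.aa_freqs))
        return "\n".join(lines) + "\n"


def assemble_descriptor(instances: list[LoopInstance],
                        name: str = "descriptor",
                        scale_factors: dict[str, float] | None = None,
                        invert_spread_weights: bool = False,
                        max_K: int = 3,
                        seed: int = 0) -> Descriptor:
    """Build a Descriptor from >= 2 equal-length loop instances.

    Positions where every instance is flagged (chain breaks, missing
    backbone) get a no-data dihedral model and neutral treatment at
    scoring time.  With ``invert_spread_weights`` the structural feature
    weights become 1/(sigma + 1) so that conserved (low-spread) positions
    weigh more; the default keeps W^F = sigma * scale.
    """
    if len(instances) < 2:
        raise ValueError("need at least two loop instances")
    n = instances[0].length
    for inst in instances:
        if inst.length != n:
            raise ValueError("loop instances must all have equal length")
    scale = {"d": 1.0, "v": 1.0, "hA": 1.0, "hD": 1.0}
    if scale_factors:
        scale.update(scale_factors)

    def spread_weight(sigma: float) -> float:
        return 1.0 / (sigma + 1.0) if invert_spread_weights else sigma

    aa_index = {aa: i for i, aa in enumerate(ALPHABET)}
    positions: list[DescriptorPosition] = []
    for i in range(n):
        feats = [inst.features[i] for inst in instances]
        usable = [f for f in feats if not f.flagged]
        counts = np.zeros(20)
        for inst in instances:
            k = aa_index.get(inst.sequence[i])
            if k is not None:
                counts[k] += 1
        aa_freqs = counts / counts.sum() if counts.sum() else np.full(20, 1 / 20)
        weight_seq = compute_seq_weight(aa_freqs) if counts.sum() else 0.0

        dpoints = [(f.phi, f.psi) for f in usable
                   if f.phi is not None and f.psi is not None]
        model = cluster_dihedrals(dpoints, max_K=max_K, seed=seed) \
            if dpoints else DihedralClusterModel.empty()
        if model.no_data:
            weight_dihedral = 0.0
        else:
            disp = wrap_diff(np.array(dpoints),
                             np.array([circular_mean([p[0] for p in dpoints]),
                                       circular_mean([p[1] for p in dpoints])])[None, :])
            sigma_d = fit_halfnormal_sigma(np.linalg.norm(disp, axis=1))
            weight_dihedral = spread_weight(sigma_d) * scale["d"]

        count_dists: dict[str, CountDistribution] = {}
        count_weights: dict[str, float] = {}
        for feat, tag in (("vdw", "v"), ("hbond_donor", "hD"),
                          ("hbond_acceptor", "hA")):
            totals = [getattr(f, f"{feat}_total") for f in usable]
            intra = [getattr(f, f"{feat}_intra") for f in usable]
            ext = [getattr(f, f"{feat}_external") for f in usable]
            if totals:
                sigma = fit_halfnormal_sigma(
                    np.abs(np.array(totals, dtype=float) - np.mean(totals)))
                dist = CountDistribution(
                    feature=feat, counts=sorted(int(t) for t in totals),
                    intra_mean=float(np.mean(intra)),
                    external_mean=float(np.mean(ext)), sigma=sigma)
                weight = spread_weight(sigma) * scale[tag]
            else:
                dist = CountDistribution(feature=feat, counts=[],
                                         intra_mean=0.0, external_mean=0.0,
                                         sigma=0.0)
                weight = 0.0
            count_dists[feat] = dist
            count_weights[feat] = weight

        positions.append(DescriptorPosition(
            aa_freqs=aa_freqs, weight_seq=weight_seq, dihedral_model=model,
            weight_dihedral=weight_dihedral, count_dists=count_dists,
            count_weights=count_weights, no_data=not usable))

    total = sum(sum(p.feature_weights().values()) for p in positions)
    for p in positions:
        p.position_weight = (sum(p.feature_weights().values()) / total
                             if total > 0 else 1.0 / n)

    return Descriptor(name=name, length=n, positions=positions,
                      scale_factors=scale, provenance=list(instances))


def save_descriptor(d: Descriptor) -> str:
    """Serialize a descriptor to versioned JSON (lossless round trip)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "name": d.name,
        "length": d.length,
        "scale_factors": dict(d.scale_factors),
        "positions": [p.to_dict() for p in d.positions],
        "provenance": [inst.to_dict() for inst in d.provenance],
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def load_descriptor(text: str) -> Descriptor:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"invalid descriptor JSON: {e}") from None
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValueError("not a descriptor file: missing schema_version")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported descriptor schema {payload['schema_version']!r}")
    return Descriptor(
        name=payload["name"], length=payload["length"],
        positions=[DescriptorPosition.from_dict(p)
                   for p in payload["positions"]],
        scale_factors=dict(payload["scale_factors"]),
        provenance=[LoopInstance.from_dict(x)
                    for x in payload["provenance"]],
    )
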