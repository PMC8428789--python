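"""Diagnostic likelihood polynomials and score-range classification.

Two printed likelihood functions drive the whole framework:

* a benign/malignant likelihood ``p1(z1, z2)`` — a quartic in the
  surface-volume ratio (SVR, z1) plus a log term in sum entropy (SE, z2);
* a stage likelihood ``p2(z3..z7)`` — linear in sphericity, LDHGLE, cluster
  prominence, small-area emphasis and strength.

They are combined by a threshold gate on (SVR, SE): nodules whose SVR and SE
both sit above empirically calibrated thresholds ``Ta``, ``Tb`` are treated as
malignant and scored with the stage likelihood; everything else is scored with
the benign/malignant likelihood.  The resulting score maps onto three classes:

    score < 0.51          -> benign
    0.51 <= score < 0.70  -> early-stage cancer
    score >= 0.70         -> advanced-stage cancer

Scores above 0.90 fall outside the advanced range's stated upper edge and are
clamped into the advanced class with a logged warning.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical lower-snake feature identifiers, in z1..z7 order.
FEATURE_NAMES = (
    "svr",
    "sum_entropy",
    "sphericity",
    "ldhgle",
    "cluster_prominence",
    "small_area_emphasis",
    "strength",
)

# benign/malignant likelihood: p1 = a + b z1 + c z1^2 + d z1^3 + e z1^4 + f ln(z2)
EQ_BM_COEFFS = (0.7478, 2.2268, -5.5856, 3.6318, -0.73065)
EQ_BM_LOG_COEFF = 1.2814e-02

# stage likelihood: p2 = c0 + c3 z3 + c4 z4 + c5 z5 + c6 z6 + c7 z7
EQ_STAGE_COEFFS = {
    "const": 1.2,
    "sphericity": -1.1348,
    "ldhgle": -7.4597e-07,
    "cluster_prominence": 3.0780e-08,
    "small_area_emphasis": 0.3917,
    "strength": -0.00361,
}

#: Class score boundaries.
BENIGN_UPPER = 0.51
EARLY_UPPER = 0.70
ADVANCED_UPPER = 0.90

#: Default gate thresholds, calibrated against the synthetic cohort generator:
#: DEFAULT_TA is the SVR at which the benign/malignant likelihood crosses 0.51
#: on its first ascending branch holding SE at the generator's malignant
#: constant (1.25); DEFAULT_TB separates the generator's benign (0.8) and
#: malignant (1.25) SE levels.
DEFAULT_TA = -0.08767435259294215
DEFAULT_TB = 1.0


class ClassLabel(str, enum.Enum):
    """Three-way diagnosis."""

    BENIGN = "benign"
    EARLY_STAGE = "early_stage"
    ADVANCED_STAGE = "advanced_stage"


class Branch(str, enum.Enum):
    """Which component of the combined likelihood was evaluated."""

    BENIGN = "benign_branch"
    STAGE = "stage_branch"


@dataclass(frozen=True)
class FeatureVector:
    """The seven radiomic feature values at one screening (z1..z7).

    ``sum_entropy`` must be strictly positive (the benign/malignant
    likelihood takes its logarithm); sphericity and small-area emphasis live
    in the unit interval; LDHGLE, cluster prominence and strength are
    nonnegative.  SVR carries no sign constraint (features enter the printed
    polynomials on a normalized scale).
    """

    svr: float
    sum_entropy: float
    sphericity: float
    ldhgle: float
    cluster_prominence: float
    small_area_emphasis: float
    strength: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"feature {name!r} must be finite, got {v!r}")
        if self.sum_entropy <= 0.0:
            raise ValueError(
                f"sum_entropy must be > 0 (the likelihood takes ln(sum_entropy)), got {self.sum_entropy}"
            )
        if not 0.0 <= self.sphericity <= 1.0:
            raise ValueError(f"sphericity must lie in [0, 1], got {self.sphericity}")
        if not 0.0 < self.small_area_emphasis <= 1.0:
            raise ValueError(f"small_area_emphasis must lie in (0, 1], got {self.small_area_emphasis}")
        for name in ("ldhgle", "cluster_prominence", "strength"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} feature values, got shape {values.shape}")
        return cls(**dict(zip(FEATURE_NAMES, values.tolist())))


@dataclass(frozen=True)
class LikelihoodConfig:
    """Gate thresholds and options of the combined likelihood.

    ``ta``/``tb`` are the SVR and SE malignancy thresholds of the gate.
    ``drop_small_terms`` omits the numerically negligible LDHGLE and cluster
    prominence terms from the stage likelihood.  ``mixed_to_stage`` routes
    mixed gate outcomes (exactly one feature above its threshold) to the
    stage branch instead of the default, conservative benign branch.
    """

    ta: float = DEFAULT_TA
    tb: float = DEFAULT_TB
    drop_small_terms: bool = False
    mixed_to_stage: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ta) and math.isfinite(self.tb)):
            raise ValueError("gate thresholds ta, tb must be finite")


def likelihood_benign_malignant(z1: float, z2: float):
    """Benign/malignant likelihood p1(z1, z2); scores < 0.51 indicate benign."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any(~np.isfinite(z1)) or np.any(~np.isfinite(z2)):
        raise ValueError("likelihood inputs must be finite")
    if np.any(z2 <= 0.0):
        raise ValueError("sum_entropy must be > 0: the ln(sum_entropy) term is undefined at 0")
    a, b, c, d, e = EQ_BM_COEFFS
    out = a + b * z1 + c * z1**2 + d * z1**3 + e * z1**4 + EQ_BM_LOG_COEFF * np.log(z2)
    return float(out) if out.ndim == 0 else out


def likelihood_stage(z3, z4, z5, z6, z7, cfg: LikelihoodConfig = LikelihoodConfig()):
    """Stage likelihood p2; [0.51, 0.70) indicates early, [0.70, 0.90] advanced."""
    z = [np.asarray(v, dtype=float) for v in (z3, z4, z5, z6, z7)]
    if any(np.any(~np.isfinite(v)) for v in z):
        raise ValueError("likelihood inputs must be finite")
    z3, z4, z5, z6, z7 = z
    c = EQ_STAGE_COEFFS
    out = c["const"] + c["sphericity"] * z3 + c["small_area_emphasis"] * z6 + c["strength"] * z7
    if not cfg.drop_small_terms:
        out = out + c["ldhgle"] * z4 + c["cluster_prominence"] * z5
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _gate_stage_mask(z1, z2, cfg: LikelihoodConfig) -> np.ndarray:
    above_a = np.asarray(z1, dtype=float) >= cfg.ta
    above_b = np.asarray(z2, dtype=float) >= cfg.tb
    if cfg.mixed_to_stage:
        return above_a | above_b
    return above_a & above_b


def combined_likelihood(z: FeatureVector, cfg: LikelihoodConfig = LikelihoodConfig()):
    """Threshold-gated likelihood: (score, branch).

    SVR >= ta AND SE >= tb selects the stage likelihood; otherwise the
    benign/malignant likelihood is evaluated.  The branch depends only on
    (svr, sum_entropy) against (ta, tb).
    """
    if bool(_gate_stage_mask(z.svr, z.sum_entropy, cfg)):
        return (
            likelihood_stage(
                z.sphericity, z.ldhgle, z.cluster_prominence, z.small_area_emphasis, z.strength, cfg
            ),
            Branch.STAGE,
        )
    return likelihood_benign_malignant(z.svr, z.sum_entropy), Branch.BENIGN


def combined_likelihood_rows(Z: np.ndarray, cfg: LikelihoodConfig = LikelihoodConfig()) -> np.ndarray:
    """Vectorized combined likelihood over an (n, 7) feature matrix.

    Rows follow :data:`FEATURE_NAMES` order.  ``sum_entropy`` is floored at a
    tiny positive value before the log so that predicted feature matrices
    produced by an unconstrained polynomial measurement model cannot leave the
    log's domain; genuine observations are validated upstream.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected an (n, 7) feature matrix, got shape {Z.shape}")
    z1, z2 = Z[:, 0], np.maximum(Z[:, 1], 1e-12)
    stage = _gate_stage_mask(z1, z2, cfg)
    out = np.empty(len(Z), dtype=float)
    if np.any(~stage):
        out[~stage] = np.atleast_1d(likelihood_benign_malignant(z1[~stage], z2[~stage]))
    if np.any(stage):
        out[stage] = np.atleast_1d(
            likelihood_stage(Z[stage, 2], Z[stage, 3], Z[stage, 4], Z[stage, 5], Z[stage, 6], cfg)
        )
    return out


def classify_score(score: float) -> ClassLabel:
    """Map a posterior diagnostic score onto the three-class partition."""
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    if score < BENIGN_UPPER:
        return ClassLabel.BENIGN
    if score < EARLY_UPPER:
        return ClassLabel.EARLY_STAGE
    if score > ADVANCED_UPPER:
        logger.warning(
            "score %.4f exceeds the advanced-stage range upper edge %.2f; clamping to advanced_stage",
            score,
            ADVANCED_UPPER,
        )
    return ClassLabel.ADVANCED_STAGE
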