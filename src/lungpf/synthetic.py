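"""Synthetic longitudinal cohorts with class-consistent feature trajectories.

The generator inverts the printed likelihood polynomials so that, noise-free,
the combined likelihood of a nodule's features at state ``u`` equals ``u``
itself.  Concretely:

* SVR follows the first ascending branch of the benign/malignant quartic:
  for any target likelihood the quartic (plus its small ln(SE) term) is
  solved for SVR by bracketed root finding on [-0.3, 0.2612], which makes
  svr(u) a smooth increasing function of the state across both regimes.
* SE is held at a sub-threshold constant (0.8) in the benign regime
  (u < 0.51) and a supra-threshold constant (1.25) in the malignant regime,
  so the gate routes benign nodules to the benign branch and malignant ones
  to the stage branch.
* In the malignant regime the stage likelihood is solved in closed form for
  sphericity (its coefficient, -1.1348, is the only printed stage
  coefficient of magnitude > 1, so sphericity can span the whole score range
  while remaining inside [0, 1]); small-area emphasis and strength are held
  at class-typical constants and LDHGLE / cluster prominence at 0 (their
  printed coefficients are negligible).  In the benign regime sphericity
  continues the same linear-in-u expression, keeping every feature a smooth
  (or exactly polynomial) function of the state — which is what makes the
  order-3 measurement fit accurate.

Gaussian measurement noise is added per feature and values are re-clipped to
their valid domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cohort_io import Trajectory
from .likelihood import (
    BENIGN_UPPER,
    EQ_BM_COEFFS,
    EQ_BM_LOG_COEFF,
    EQ_STAGE_COEFFS,
    ClassLabel,
    FeatureVector,
)
from .measurement_model import clip_to_feature_domains

# -- generator constants (see module docstring and docs/methods.md) ---------
SE_BENIGN = 0.8  # sub-threshold sum entropy, benign regime
SE_MALIGNANT = 1.25  # supra-threshold sum entropy, malignant regime
SAE_CONST = 0.5  # small-area emphasis, all nodules
STRENGTH_CONST = 73.0  # strength, all nodules
#: bracket of the first ascending branch of the benign/malignant quartic
SVR_BRACKET = (-0.3, 0.2612236728044541)
#: malignant ramp paths start here (benign paths stay flat at their target)
RAMP_START = 0.08

# stage likelihood with z4 = z5 = 0, z6, z7 fixed:  p2 = STAGE_INTERCEPT + c3 * z3
STAGE_INTERCEPT = (
    EQ_STAGE_COEFFS["const"]
    + EQ_STAGE_COEFFS["small_area_emphasis"] * SAE_CONST
    + EQ_STAGE_COEFFS["strength"] * STRENGTH_CONST
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort sizes, noise scales and per-class target-state ranges.

    The class ranges are insets of the diagnostic score ranges (e.g.
    [0.52, 0.68] inside the early-stage range [0.51, 0.70)) so that
    measurement noise does not straddle a class boundary.  Default cohort
    composition mirrors the study's screening cohort: 70 benign, 70
    early-stage, 60 advanced-stage nodules over K = 5 half-yearly intervals.
    """

    n_benign: int = 70
    n_early: int = 70
    n_advanced: int = 60
    state_noise_sd: float = 0.01
    feature_noise_sd: float = 0.01
    benign_range: tuple = (0.05, 0.45)
    early_range: tuple = (0.52, 0.68)
    advanced_range: tuple = (0.72, 0.88)
    seed: int = 0
    K: int = 5
    n_training: int = 500

    def __post_init__(self) -> None:
        if min(self.n_benign, self.n_early, self.n_advanced) < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.state_noise_sd < 0 or self.feature_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        ranges = (self.benign_range, self.early_range, self.advanced_range)
        for lo, hi in ranges:
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"class range ({lo}, {hi}) must be ordered within [0, 1]")
        if not (self.benign_range[1] < self.early_range[0] < self.early_range[1] < self.advanced_range[0]):
            raise ValueError("class ranges must be disjoint and ordered benign < early < advanced")
        if self.K < 2:
            raise ValueError("K must be >= 2")


def _solve_svr(target: float) -> float:
    """Invert the benign/malignant quartic on its first ascending branch."""
    a, b, c, d, e = EQ_BM_COEFFS
    lo, hi = SVR_BRACKET

    def f(z):
        return a + b * z + c * z**2 + d * z**3 + e * z**4 - target

    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"likelihood target {target:.6f} is outside the solvable range of the "
            f"SVR bracket [{lo}, {hi}]"
        )
    return brentq(f, lo, hi, xtol=1e-12)


def _noise_free_features(u: float) -> np.ndarray:
    """Feature row (z1..z7) whose combined likelihood equals u exactly."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"state must lie in [0, 1], got {u}")
    benign = u < BENIGN_UPPER
    se = SE_BENIGN if benign else SE_MALIGNANT
    svr = _solve_svr(u - EQ_BM_LOG_COEFF * math.log(se))
    if benign:
        # sphericity continues the malignant-regime line so z3(u) is globally linear
        z3 = (STAGE_INTERCEPT - u) / (-EQ_STAGE_COEFFS["sphericity"])
    else:
        # closed-form stage solve:  u = STAGE_INTERCEPT + c3 * z3
        z3 = (u - STAGE_INTERCEPT) / EQ_STAGE_COEFFS["sphericity"]
    if not 0.0 <= z3 <= 1.0:
        raise ValueError(
            f"stage solve produced sphericity {z3:.4f} outside [0, 1] for state {u:.4f}"
        )
    return np.array([svr, se, z3, 0.0, 0.0, SAE_CONST, STRENGTH_CONST])


def features_for_state(u: float, cfg: SyntheticConfig, rng: np.random.Generator) -> FeatureVector:
    """Generate one feature vector for state ``u``: inverse solve plus noise.

    Noise-free (``feature_noise_sd`` = 0) the combined likelihood of the
    output reproduces ``u`` to 1e-6 and the gate branch matches the regime of
    ``u``.  With noise, independent Gaussian perturbations of the configured
    sd are added to every feature and values are re-clipped to their valid
    domains.
    """
    row = _noise_free_features(float(u))
    if cfg.feature_noise_sd > 0:
        row = row + rng.normal(0.0, cfg.feature_noise_sd, size=row.shape)
        row = clip_to_feature_domains(row[None, :])[0]
    return FeatureVector.from_array(row)


def generate_state_path(target: float, K: int, state_noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth state path ending at ``target``.

    Benign targets (< 0.51) give a flat-low path at the target; malignant
    targets a linear ramp from RAMP_START to the target.  Truncated-Gaussian
    jitter of sd ``state_noise_sd`` is applied to the interior of the path
    (the final state stays exactly on target) and values are clipped to
    [0, 1].
    """
    target = float(target)
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target state must lie in [0, 1], got {target}")
    if target < BENIGN_UPPER:
        mean = np.full(K, target)
    else:
        mean = np.linspace(min(RAMP_START, target), target, K)
    path = mean.copy()
    if state_noise_sd > 0:
        path[:-1] = path[:-1] + rng.normal(0.0, state_noise_sd, size=K - 1)
    return np.clip(path, 0.0, 1.0)


def generate_cohort(cfg: SyntheticConfig):
    """Generate the synthetic cohort: trajectories with truth labels and state paths.

    Per nodule, a final-state target is drawn uniformly in its class range,
    the ground-truth state path is built, and one feature vector is emitted
    per interval.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    spec = [
        (ClassLabel.BENIGN, cfg.n_benign, cfg.benign_range),
        (ClassLabel.EARLY_STAGE, cfg.n_early, cfg.early_range),
        (ClassLabel.ADVANCED_STAGE, cfg.n_advanced, cfg.advanced_range),
    ]
    trajectories = []
    counter = 0
    for label, size, (lo, hi) in spec:
        for _ in range(size):
            counter += 1
            nodule_id = f"N{counter:04d}"
            target = rng.uniform(lo, hi)
            path = generate_state_path(target, cfg.K, cfg.state_noise_sd, rng)
            points = [features_for_state(u, cfg, rng) for u in path]
            trajectories.append(
                Trajectory(
                    nodule_id=nodule_id,
                    points=points,
                    truth_label=label,
                    true_states=[float(v) for v in path],
                )
            )
    return trajectories


def generate_training_pairs(n: int, cfg: SyntheticConfig, rng: np.random.Generator):
    """(state, FeatureVector) pairs with states uniform on [0, 1].

    Suitable as input to measurement-model fitting; features carry the
    configured measurement noise.
    """
    if n < 1:
        raise ValueError(f"pair count must be >= 1, got {n}")
    states = rng.uniform(0.0, 1.0, size=n)
    return [(float(u), features_for_state(u, cfg, rng)) for u in states]


def truth_table(trajectories) -> "pd.DataFrame":
    """Truth CSV frame: nodule_id, truth_label, true_state_k1..kK."""
    import pandas as pd

    rows = []
    for t in trajectories:
        row = {"nodule_id": t.nodule_id, "truth_label": t.truth_label.value if t.truth_label else ""}
        if t.true_states:
            for k, u in enumerate(t.true_states, start=1):
                row[f"true_state_k{k}"] = u
        rows.append(row)
    return pd.DataFrame(rows)
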