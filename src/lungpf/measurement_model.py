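"""Polynomial measurement model: latent state -> expected radiomic features.

Each of the seven features is modelled as an independent order-M polynomial in
the malignancy state u,

    z_q(u) = sum_{m=0..M} p_{qm} u**m,

with coefficients fit by ordinary least squares on a training set of
(state, feature-vector) pairs and a per-feature residual standard deviation
recorded as the measurement-noise scale.  The default order is M = 3 (cubic),
which the filter uses unless configured otherwise; fits use numpy's
SVD-backed polynomial least squares for conditioning on [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .likelihood import FEATURE_NAMES, FeatureVector


@dataclass(frozen=True)
class MeasurementModel:
    """Per-feature polynomial coefficients (constant term first) and noise scales."""

    order: int
    coeffs: dict  # feature name -> tuple of order+1 floats
    noise_sd: dict  # feature name -> float >= 0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"polynomial order must be >= 1, got {self.order}")
        for name in FEATURE_NAMES:
            if name not in self.coeffs:
                raise ValueError(f"missing coefficients for feature {name!r}")
            c = self.coeffs[name]
            if len(c) != self.order + 1 or any(not math.isfinite(v) for v in c):
                raise ValueError(
                    f"feature {name!r} needs {self.order + 1} finite coefficients, got {c!r}"
                )
            sd = self.noise_sd.get(name)
            if sd is None or not math.isfinite(sd) or sd < 0.0:
                raise ValueError(f"feature {name!r} needs a finite noise_sd >= 0, got {sd!r}")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "order": self.order,
            "coeffs": {n: list(self.coeffs[n]) for n in FEATURE_NAMES},
            "noise_sd": {n: self.noise_sd[n] for n in FEATURE_NAMES},
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MeasurementModel":
        doc = json.loads(text)
        return cls(
            order=int(doc["order"]),
            coeffs={n: tuple(float(v) for v in doc["coeffs"][n]) for n in FEATURE_NAMES},
            noise_sd={n: float(doc["noise_sd"][n]) for n in FEATURE_NAMES},
        )

    def coeff_matrix(self) -> np.ndarray:
        """(order+1, 7) coefficient matrix, columns in FEATURE_NAMES order."""
        return np.column_stack([self.coeffs[n] for n in FEATURE_NAMES])


def fit_measurement_model(pairs: Sequence, order: int = 3) -> MeasurementModel:
    """Least-squares fit of the per-feature polynomials from (state, features) pairs.

    ``pairs`` is a sequence of (u, FeatureVector) with u in [0, 1] (floats or
    MalignancyState).  Requires at least ``order + 1`` distinct states;
    ``noise_sd`` is the per-feature residual standard deviation (zero when the
    distinct-state count equals order + 1, i.e. exact interpolation).
    """
    if order < 1:
        raise ValueError(f"polynomial order must be >= 1, got {order}")
    states = np.array([float(getattr(u, "u", u)) for u, _ in pairs], dtype=float)
    Z = np.array(
        [z.as_array() if isinstance(z, FeatureVector) else np.asarray(z, dtype=float) for _, z in pairs]
    )
    n_distinct = np.unique(states).size
    if n_distinct < order + 1:
        raise ValueError(
            f"rank-deficient fit: order {order} needs at least {order + 1} distinct states, "
            f"got {n_distinct}"
        )
    coeffs = {}
    noise_sd = {}
    dof = max(len(states) - (order + 1), 1)
    for j, name in enumerate(FEATURE_NAMES):
        c = npoly.polyfit(states, Z[:, j], order)
        resid = Z[:, j] - npoly.polyval(states, c)
        coeffs[name] = tuple(float(v) for v in c)
        if n_distinct == order + 1:
            noise_sd[name] = 0.0
        else:
            noise_sd[name] = float(np.sqrt(np.sum(resid**2) / dof))
    return MeasurementModel(order=order, coeffs=coeffs, noise_sd=noise_sd)


def predict_feature_matrix(u: np.ndarray, model: MeasurementModel) -> np.ndarray:
    """Noise-free expected features at states ``u``: an (n, 7) matrix."""
    u = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("states must be finite and in [0, 1]")
    # Vandermonde (n, order+1) @ (order+1, 7)
    V = np.vander(u, N=model.order + 1, increasing=True)
    return V @ model.coeff_matrix()


#: smallest admissible value for strictly-positive / half-open-domain features
_EPS = 1e-9


def clip_to_feature_domains(Z: np.ndarray) -> np.ndarray:
    """Clip an (n, 7) feature matrix into the valid per-feature domains.

    sum_entropy and small_area_emphasis are floored at a tiny epsilon,
    sphericity and small_area_emphasis capped at 1, and the nonnegative
    features floored at 0; svr is unconstrained.
    """
    Z = np.array(Z, dtype=float)
    Z[:, 1] = np.maximum(Z[:, 1], _EPS)  # sum_entropy > 0
    Z[:, 2] = np.clip(Z[:, 2], 0.0, 1.0)  # sphericity
    Z[:, 3] = np.maximum(Z[:, 3], 0.0)  # ldhgle
    Z[:, 4] = np.maximum(Z[:, 4], 0.0)  # cluster_prominence
    Z[:, 5] = np.clip(Z[:, 5], _EPS, 1.0)  # small_area_emphasis
    Z[:, 6] = np.maximum(Z[:, 6], 0.0)  # strength
    return Z


def predict_features(u, model: MeasurementModel) -> FeatureVector:
    """Noise-free expected feature vector at a single state ``u``.

    Raw polynomial values are clipped into the valid feature domains (a
    fitted polynomial may overshoot a bounded domain slightly at the edges of
    [0, 1]) before packing into a validated :class:`FeatureVector`.
    """
    row = predict_feature_matrix(np.array([float(getattr(u, "u", u))]), model)
    return FeatureVector.from_array(clip_to_feature_domains(row)[0])
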