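"""Latent malignancy state and its transition prior.

The diagnostic state of a nodule is a scalar score ``u`` in [0, 1]; the
score ranges <0.51 / [0.51, 0.70) / >=0.70 correspond to benign, early-stage
and advanced-stage disease (see :mod:`lungpf.likelihood`).  Between two
consecutive screenings the state is assumed to move according to an
exponential-power kernel

    p(u_k | u_{k-1})  ∝  exp(-|u_k - u_{k-1}|**alpha / alpha)

restricted to [0, 1], with a single shape parameter ``alpha`` controlling the
kernel.  Note that for every ``alpha`` the kernel's characteristic scale is of
order one on the unit interval, so the transition prior is only weakly
informative; the filter's information comes primarily from the measurement
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma


@dataclass(frozen=True)
class MalignancyState:
    """Scalar diagnostic score ``u`` in [0, 1]."""

    u: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.u):
            raise ValueError(f"malignancy state must be finite, got {self.u!r}")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"malignancy state must lie in [0, 1], got {self.u}")


@dataclass(frozen=True)
class TransitionParams:
    """Shape parameter ``alpha`` of the transition kernel.

    ``alpha`` must be positive.  The default 0.1 yields an almost flat
    (near-uniform) transition prior on [0, 1].
    """

    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0.0):
            raise ValueError(f"alpha must be a positive finite scalar, got {self.alpha!r}")


def _as_state_value(u) -> float:
    if isinstance(u, MalignancyState):
        return u.u
    u = float(u)
    if not math.isfinite(u):
        raise ValueError(f"state value must be finite, got {u!r}")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"state value must lie in [0, 1], got {u}")
    return u


def transition_density(u_k, u_prev, params: TransitionParams) -> float:
    """Unnormalized transition kernel exp(-|u_k - u_prev|**alpha / alpha).

    Symmetric in its two state arguments; equals 1 iff ``u_k == u_prev``.
    """
    a = params.alpha
    uk = _as_state_value(u_k)
    up = _as_state_value(u_prev)
    return math.exp(-abs(uk - up) ** a / a)


def transition_density_matrix(u_to: np.ndarray, u_from: np.ndarray, params: TransitionParams) -> np.ndarray:
    """Vectorized kernel evaluation: entry [i, j] = density of u_to[i] given u_from[j]."""
    a = params.alpha
    d = np.abs(np.asarray(u_to, dtype=float)[:, None] - np.asarray(u_from, dtype=float)[None, :])
    return np.exp(-(d**a) / a)


def sample_transition(u_prev, params: TransitionParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` next-interval states from the truncated transition kernel.

    Sampling is exact: with ``y = |delta|**alpha`` the kernel density of the
    unrestricted jump magnitude becomes Gamma(1/alpha, scale=alpha) truncated
    to y in [0, 1], which is inverted through the gamma ppf; the sign is
    symmetric and proposals falling outside [0, 1] are redrawn, which realizes
    the restriction of the kernel to the state domain without distorting its
    shape.  ``u_prev`` may be a scalar or an array of length ``n`` (one
    previous state per sample).  Deterministic given ``rng``'s state.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    a = params.alpha
    shape = 1.0 / a
    prev = np.asarray(
        [_as_state_value(u_prev)] * n
        if np.isscalar(u_prev) or isinstance(u_prev, MalignancyState)
        else [float(v) for v in u_prev],
        dtype=float,
    )
    if prev.shape != (n,):
        raise ValueError(f"u_prev must be scalar or length-{n}, got shape {prev.shape}")
    if np.any(~np.isfinite(prev)) or np.any(prev < 0.0) or np.any(prev > 1.0):
        raise ValueError("u_prev values must be finite and in [0, 1]")

    # mass of the magnitude kernel below |delta| = 1
    c1 = _gamma.cdf(1.0, shape, scale=a)
    out = np.empty(n, dtype=float)
    todo = np.arange(n)
    # acceptance >= 1/2 per round (worst case u_prev at a boundary)
    while todo.size:
        y = _gamma.ppf(rng.random(todo.size) * c1, shape, scale=a)
        mag = y ** (1.0 / a)
        sign = np.where(rng.random(todo.size) < 0.5, -1.0, 1.0)
        cand = prev[todo] + sign * mag
        ok = (cand >= 0.0) & (cand <= 1.0)
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return out
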