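"""Longitudinal cohort tables and spline densification.

Cohorts are long-format RFC-4180 CSV files with one row per (nodule,
screening): columns ``nodule_id, time_index`` plus the seven feature columns
(and optionally ``truth_label`` for synthetic/validation cohorts).  Nodules
observed at three annual screenings are densified to five half-yearly points
by per-feature natural cubic splines through the three annual values, so the
filter always sees K = 5 intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .likelihood import FEATURE_NAMES, ClassLabel, FeatureVector
from .measurement_model import clip_to_feature_domains

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("nodule_id", "time_index") + FEATURE_NAMES

#: number of screening intervals after densification
K_DENSE = 5


@dataclass
class Trajectory:
    """Ordered per-nodule feature sequence, interval indices k = 1..K."""

    nodule_id: str
    points: list  # list[FeatureVector], index i is interval k = i + 1
    truth_label: Optional[ClassLabel] = None
    true_states: Optional[list] = field(default=None)  # ground-truth u per interval, if known

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError(f"trajectory {self.nodule_id!r} has no points")
        for p in self.points:
            if not isinstance(p, FeatureVector):
                raise TypeError("trajectory points must be FeatureVector instances")

    def __len__(self) -> int:
        return len(self.points)

    def feature_matrix(self) -> np.ndarray:
        """(K, 7) matrix of observed features in FEATURE_NAMES order."""
        return np.array([p.as_array() for p in self.points])


def read_cohort(path) -> list:
    """Read a long-format cohort CSV into a list of :class:`Trajectory`.

    Raises on missing columns, non-numeric feature cells, duplicated
    (nodule_id, time_index) rows and invalid feature values.  An empty table
    with a valid header yields an empty cohort.
    """
    df = pd.read_csv(path, dtype={"nodule_id": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required column(s): {', '.join(missing)}")
    for col in ("time_index",) + FEATURE_NAMES:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header line + 1-based
            raise ValueError(f"non-numeric value in column {col!r} at file line {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"missing value in column {col!r} at file line {row}")
        df[col] = coerced
    dup = df.duplicated(subset=["nodule_id", "time_index"])
    if dup.any():
        pairs = df.loc[dup, ["nodule_id", "time_index"]].to_records(index=False).tolist()
        raise ValueError(f"duplicated (nodule_id, time_index) rows: {pairs}")

    trajectories = []
    for nodule_id, grp in df.groupby("nodule_id", sort=True):
        grp = grp.sort_values("time_index")
        label = None
        if "truth_label" in grp.columns:
            raw = grp["truth_label"].dropna().unique()
            if len(raw) > 1:
                raise ValueError(f"nodule {nodule_id!r} carries conflicting truth labels: {raw}")
            if len(raw) == 1:
                label = ClassLabel(raw[0])
        points = []
        for _, row in grp.iterrows():
            try:
                points.append(FeatureVector(**{n: float(row[n]) for n in FEATURE_NAMES}))
            except ValueError as exc:
                raise ValueError(f"nodule {nodule_id!r}, time_index {row['time_index']}: {exc}") from exc
        trajectories.append(Trajectory(nodule_id=str(nodule_id), points=points, truth_label=label))
    return trajectories


def write_cohort(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories back to the long-format cohort CSV."""
    rows = []
    any_label = any(t.truth_label is not None for t in trajectories)
    for t in trajectories:
        for k, p in enumerate(t.points, start=1):
            row = {"nodule_id": t.nodule_id, "time_index": k}
            row.update({n: getattr(p, n) for n in FEATURE_NAMES})
            if any_label:
                row["truth_label"] = t.truth_label.value if t.truth_label else ""
            rows.append(row)
    cols = list(REQUIRED_COLUMNS) + (["truth_label"] if any_label else [])
    # %.17g guarantees bit-faithful float64 round trips through the CSV
    pd.DataFrame(rows, columns=cols).to_csv(
        path, index=False, lineterminator="\r\n", float_format="%.17g"
    )


def densify_trajectory(trajectory: Trajectory) -> Trajectory:
    """Densify three annual readings to five half-yearly intervals.

    Each feature is interpolated by a natural cubic spline through its three
    annual values (years 0, 1, 2) and evaluated at the two midpoints; the
    original observations are preserved exactly and the output is re-indexed
    k = 1..5.  A five-point trajectory passes through unchanged; any other
    length is an error.  Interpolated values that leave a feature's valid
    domain are clipped with a logged warning.
    """
    if len(trajectory) == K_DENSE:
        return trajectory
    if len(trajectory) != 3:
        raise ValueError(
            f"nodule {trajectory.nodule_id!r}: densification needs exactly 3 annual points "
            f"(or {K_DENSE} already-densified), got {len(trajectory)}"
        )
    years = np.array([0.0, 1.0, 2.0])
    Z = trajectory.feature_matrix()  # (3, 7)
    spline = CubicSpline(years, Z, axis=0, bc_type="natural")
    mid = spline(np.array([0.5, 1.5]))  # (2, 7)
    clipped = clip_to_feature_domains(mid)
    if not np.array_equal(clipped, mid):
        logger.warning(
            "nodule %s: spline midpoints left a feature's valid domain and were clipped",
            trajectory.nodule_id,
        )
    dense = np.empty((K_DENSE, Z.shape[1]))
    dense[0], dense[2], dense[4] = Z[0], Z[1], Z[2]  # originals preserved bitwise
    dense[1], dense[3] = clipped[0], clipped[1]
    points = [FeatureVector.from_array(row) for row in dense]
    return Trajectory(
        nodule_id=trajectory.nodule_id,
        points=points,
        truth_label=trajectory.truth_label,
        true_states=None,
    )


def densify_cohort(trajectories: Sequence[Trajectory]) -> list:
    return [densify_trajectory(t) for t in trajectories]
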