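"""Discrete cell-state assignment.

Two labelling schemes are provided: High/Mid/Low compartments from intensity
quartiles (steady-state cultures) and a two-cluster k-means split into
PrE/NEDiff (differentiation cultures). Quartile thresholds fitted on one
condition can be reused to label another, so a treated dataset is scored
against the control's cut points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigError, DataError, DegenerateClusterError, InsufficientDataError
from .tracks_io import LineageForest, mean_cell_intensity

QUARTILE_STATES = ("Low", "Mid", "High")
FATE_STATES = ("NEDiff", "PrE")


@dataclass(frozen=True)
class CompartmentThresholds:
    """Intensity cut points separating Low / Mid / High compartments.

    ``q_low`` and ``q_high`` are the 25th and 75th percentiles (linear
    interpolation) of per-cell mean intensities on the source condition.
    """

    q_low: float
    q_high: float
    source_condition: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q_low) and math.isfinite(self.q_high)):
            raise DataError("thresholds must be finite")
        if self.q_low > self.q_high:
            raise DataError(f"q_low {self.q_low} > q_high {self.q_high}")


@dataclass
class StateLabeling:
    """Per-cell discrete states plus the fitted cut points or centroids."""

    labels: dict[str, str]
    method: str  # "quartile" | "kmeans"
    thresholds: CompartmentThresholds | None = None
    centroids: tuple[float, ...] | None = None
    mean_intensities: dict[str, float] = field(default_factory=dict)

    def states(self) -> tuple[str, ...]:
        canonical = QUARTILE_STATES if self.method == "quartile" else FATE_STATES
        observed = set(self.labels.values())
        if observed <= set(canonical):
            return canonical
        return tuple(sorted(observed))

    def __getitem__(self, cell_id: str) -> str:
        return self.labels[cell_id]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.labels


def fit_quartile_thresholds(
    mean_intensities, source_condition: str = ""
) -> CompartmentThresholds:
    """25th/75th percentile cut points of per-cell mean intensities."""
    values = np.asarray(list(mean_intensities), dtype=float)
    if values.size < 4:
        raise InsufficientDataError(
            f"need >= 4 values to fit quartiles, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite intensity values")
    q_low, q_high = np.percentile(values, [25, 75])  # linear interpolation
    return CompartmentThresholds(float(q_low), float(q_high), source_condition)


def assign_compartment(mean_intensity: float, thresholds: CompartmentThresholds) -> str:
    """High above ``q_high``, Low below ``q_low``, Mid otherwise (ties -> Mid)."""
    if not math.isfinite(mean_intensity):
        raise DataError(f"non-finite intensity {mean_intensity}")
    if mean_intensity > thresholds.q_high:
        return "High"
    if mean_intensity < thresholds.q_low:
        return "Low"
    return "Mid"


def kmeans_fate_split(
    mean_intensities: dict[str, float], seed: int = 0, n_init: int = 10
) -> StateLabeling:
    """Two-cluster k-means on per-cell mean intensities.

    The cluster with the higher centroid is labelled PrE, the other NEDiff.
    Deterministic under a fixed seed; invariant to input order because cells
    are processed in sorted id order.
    """
    ids = sorted(mean_intensities)
    values = np.array([mean_intensities[c] for c in ids], dtype=float)
    if np.unique(values).size < 2:
        raise DegenerateClusterError("all intensities identical; cannot split")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    pre_cluster = int(np.argmax(centers))
    labels = {
        cid: ("PrE" if a == pre_cluster else "NEDiff")
        for cid, a in zip(ids, assignments)
    }
    return StateLabeling(
        labels=labels,
        method="kmeans",
        centroids=tuple(sorted(float(c) for c in centers)),
        mean_intensities=dict(mean_intensities),
    )


def label_forest(
    forest: LineageForest,
    method: str = "quartile",
    thresholds: CompartmentThresholds | None = None,
    seed: int = 0,
) -> StateLabeling:
    """Label every cell of a (pruned) forest from its mean cycle intensity.

    With ``method='quartile'`` the thresholds are fitted on this forest unless
    pre-fitted ones are passed in (cross-condition labelling). With
    ``method='kmeans'`` a fresh two-way split is fitted.
    """
    means = {cid: mean_cell_intensity(tr) for cid, tr in forest.tracks.items()}
    if not means:
        return StateLabeling(labels={}, method=method, thresholds=thresholds)
    if method == "quartile":
        if thresholds is None:
            thresholds = fit_quartile_thresholds(
                means.values(), source_condition=forest.condition_label
            )
        labels = {cid: assign_compartment(v, thresholds) for cid, v in means.items()}
        return StateLabeling(
            labels=labels, method="quartile", thresholds=thresholds,
            mean_intensities=means,
        )
    if method == "kmeans":
        if thresholds is not None:
            raise ConfigError("thresholds are not used with method='kmeans'")
        return kmeans_fate_split(means, seed=seed)
    raise ConfigError(f"unknown labelling method {method!r}")
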