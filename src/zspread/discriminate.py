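"""Migration-vs-proliferation discrimination and automatic classification.

Two per-well read-outs carry complementary information: the
covered-electrode count tracks how far cells have spread (migration)
and the covered-only median maximum relative impedance tracks how much
cell material sits on the reached electrodes (cell amount, i.e.
proliferation).  Two cuts on these axes define four quadrants:

    Q1  low migration,  low proliferation
    Q2  low migration,  high proliferation
    Q3  high migration, high proliferation
    Q4  high migration, low proliferation

The cuts are calibrated from reference wells — phenotypes of known
high/low migration propensity, each with and without proliferation
suppression (mitomycin C) — as between-group midpoints of the endpoint
values; without references they fall back to the documented defaults
(20 electrodes, 110 %).

For automatic classification each well is condensed into 12 features
(covered counts at six time points, then medians at the same six time
points), z-scored, reduced to three principal components and soft-
clustered with fuzzy c-means into four clusters matching the four
reference groups.  New wells are assigned by projecting onto the
trained basis and evaluating memberships against the fixed centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .analysis import WellSummary
from .fcm import fcm_memberships, fuzzy_cmeans

__all__ = [
    "DEFAULT_COVERAGE_CUT",
    "DEFAULT_IMPEDANCE_CUT",
    "DEFAULT_FEATURE_TIMES_H",
    "QuadrantThresholds",
    "Quadrant",
    "FeatureVector",
    "ReferenceModel",
    "calibrate_thresholds",
    "assign_quadrant",
    "build_features",
    "fit_reference_model",
    "classify",
    "classification_report",
]

DEFAULT_COVERAGE_CUT = 20.0  # electrodes
DEFAULT_IMPEDANCE_CUT = 110.0  # % median maximum relative impedance
DEFAULT_FEATURE_TIMES_H = (24.0, 48.0, 72.0, 96.0, 120.0, 144.0)


@dataclass(frozen=True)
class QuadrantThresholds:
    coverage_cut: float = DEFAULT_COVERAGE_CUT
    impedance_cut: float = DEFAULT_IMPEDANCE_CUT

    def __post_init__(self) -> None:
        if self.coverage_cut <= 0 or self.impedance_cut <= 0:
            raise ValueError("quadrant cuts must be positive")


class Quadrant(str, Enum):
    Q1 = "Q1"  # low migration, low proliferation
    Q2 = "Q2"  # low migration, high proliferation
    Q3 = "Q3"  # high migration, high proliferation
    Q4 = "Q4"  # high migration, low proliferation
    UNDEFINED = "undefined"  # no covered electrode -> no median


@dataclass
class FeatureVector:
    """Ordered 12-vector: covered counts at six time points followed by
    the medians at the same six time points; missing medians are
    imputed with 0 (a well with no covered electrode carries no cell
    signal) and flagged."""

    values: np.ndarray
    well_id: str = ""
    label: str = ""
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("feature vector must have exactly 12 entries")
        if self.imputed is None:
            self.imputed = np.zeros(12, dtype=bool)


def calibrate_thresholds(
    summaries: list[WellSummary],
    high_migration: list[bool],
    proliferating: list[bool],
    endpoint_h: float = 144.0,
    allow_fallback: bool = True,
) -> QuadrantThresholds:
    """Midpoint calibration of the quadrant cuts from labelled
    reference wells.

    coverage_cut: midpoint between the mean endpoint covered count of
    the low- and high-migration groups.  impedance_cut: midpoint
    between the mean endpoint medians of the proliferation-suppressed
    and proliferating groups.  With no summaries at all the documented
    defaults (20, 110) are returned when ``allow_fallback``.
    """
    if not summaries:
        if allow_fallback:
            return QuadrantThresholds()
        raise ValueError("no reference summaries and fallback disabled")
    if not (len(summaries) == len(high_migration) == len(proliferating)):
        raise ValueError("labels must match summaries")
    counts = np.array([s.at_time(endpoint_h)[0] for s in summaries], float)
    medians = np.array([s.at_time(endpoint_h)[1] for s in summaries], float)
    medians = np.nan_to_num(medians, nan=0.0)
    hm = np.asarray(high_migration, bool)
    pr = np.asarray(proliferating, bool)

    def _midpoint(values, mask, what):
        if mask.all() or (~mask).all():
            if allow_fallback:
                return None
            raise ValueError(f"need both groups to calibrate the {what} cut")
        return (values[mask].mean() + values[~mask].mean()) / 2.0

    cov = _midpoint(counts, hm, "coverage")
    imp = _midpoint(medians, pr, "impedance")
    return QuadrantThresholds(
        coverage_cut=DEFAULT_COVERAGE_CUT if cov is None else float(cov),
        impedance_cut=DEFAULT_IMPEDANCE_CUT if imp is None else float(imp),
    )


def assign_quadrant(
    covered: float,
    med_max_ri: float,
    thr: QuadrantThresholds = QuadrantThresholds(),
) -> Quadrant:
    """Quadrant of one (covered count, median) point; boundaries are
    inclusive on the high side.  A missing (NaN) median yields
    ``Quadrant.UNDEFINED``."""
    if covered < 0:
        raise ValueError("covered count must be >= 0")
    if np.isnan(med_max_ri):
        return Quadrant.UNDEFINED
    mig_high = covered >= thr.coverage_cut
    pro_high = med_max_ri >= thr.impedance_cut
    if mig_high:
        return Quadrant.Q3 if pro_high else Quadrant.Q4
    return Quadrant.Q2 if pro_high else Quadrant.Q1


def build_features(
    ws: WellSummary,
    time_points: tuple[float, ...] = DEFAULT_FEATURE_TIMES_H,
) -> FeatureVector:
    """Assemble the 12 clustering inputs from one well summary:
    covered counts at the six time points, then the corresponding
    medians (missing medians imputed with 0 and flagged)."""
    if len(time_points) != 6:
        raise ValueError("exactly six feature time points are required")
    counts = np.empty(6)
    medians = np.empty(6)
    imput = np.zeros(12, dtype=bool)
    for i, t in enumerate(time_points):
        c, m = ws.at_time(t)  # raises on a missing time point
        counts[i] = c
        if np.isnan(m):
            medians[i] = 0.0
            imput[6 + i] = True
        else:
            medians[i] = m
    return FeatureVector(
        values=np.concatenate([counts, medians]),
        well_id=ws.well_id,
        label=ws.label,
        imputed=imput,
    )


@dataclass
class ReferenceModel:
    """Frozen standardization + PCA basis + fuzzy c-means centres
    fitted on reference wells."""

    feature_mean: np.ndarray  # (12,)
    feature_sd: np.ndarray  # (12,)
    kept_features: np.ndarray  # bool (12,); zero-variance features dropped
    components: np.ndarray  # (dims, n_kept) PCA loadings (orthonormal rows)
    explained_variance_ratio: np.ndarray
    centers: np.ndarray  # (k, dims)
    m: float
    training_memberships: np.ndarray  # (n_train, k)
    training_well_ids: list[str]
    training_labels: list[str]
    cluster_labels: list[str]  # majority training label per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    @property
    def n_dims(self) -> int:
        return self.centers.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """z-score with the training statistics and project onto the
        training PCA basis."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        if v.shape[1] != self.feature_mean.size:
            raise ValueError(
                f"expected {self.feature_mean.size} features, got {v.shape[1]}"
            )
        z = (v - self.feature_mean) / self.feature_sd
        return z[:, self.kept_features] @ self.components.T


def fit_reference_model(
    features: list[FeatureVector],
    k: int = 4,
    dims: int = 3,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 20,
) -> ReferenceModel:
    """Fit the reference pipeline: per-feature z-score, PCA to ``dims``
    dimensions, fuzzy c-means with ``k`` clusters (best of
    ``n_restarts`` seeded restarts).

    Zero-variance features are dropped with a warning; fewer samples
    than clusters is an error.
    """
    if len(features) < k:
        raise ValueError(f"need at least k={k} feature vectors, got {len(features)}")
    x = np.stack([fv.values for fv in features])
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    kept = sd > 0
    if not np.all(kept):
        import warnings

        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance feature(s)",
            stacklevel=2,
        )
    sd_safe = np.where(kept, sd, 1.0)
    z = ((x - mean) / sd_safe)[:, kept]
    dims_eff = min(dims, z.shape[1], len(features))
    pca = PCA(n_components=dims_eff, svd_solver="full", random_state=seed)
    y = pca.fit_transform(z)
    fit = fuzzy_cmeans(
        y, k=k, m=m, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
    )
    labels = [fv.label for fv in features]
    hard = np.argmax(fit.memberships, axis=1)
    cluster_labels = []
    for c in range(k):
        members = [labels[i] for i in range(len(labels)) if hard[i] == c]
        cluster_labels.append(
            max(set(members), key=members.count) if members else ""
        )
    return ReferenceModel(
        feature_mean=mean,
        feature_sd=sd_safe,
        kept_features=kept,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        centers=fit.centers,
        m=m,
        training_memberships=fit.memberships,
        training_well_ids=[fv.well_id for fv in features],
        training_labels=labels,
        cluster_labels=cluster_labels,
    )


def classify(
    model: ReferenceModel, fv: FeatureVector
) -> tuple[np.ndarray, int]:
    """Memberships of one well against the trained centres and the
    hard cluster label (argmax membership; ties go to the lowest
    cluster index)."""
    y = model.transform(fv.values)
    u = fcm_memberships(y, model.centers, model.m)[0]
    return u, int(np.argmax(u))


def classification_report(
    model: ReferenceModel,
    features: list[FeatureVector],
    summaries: list[WellSummary] | None = None,
    thresholds: QuadrantThresholds = QuadrantThresholds(),
    endpoint_h: float = 144.0,
) -> pd.DataFrame:
    """Tidy per-well report: memberships, hard cluster (with its
    majority training label) and, when summaries are given, the
    endpoint quadrant."""
    rows = []
    for i, fv in enumerate(features):
        u, hard = classify(model, fv)
        row = {
            "well_id": fv.well_id,
            "group": fv.label,
            **{f"membership_{c}": u[c] for c in range(model.n_clusters)},
            "hard_cluster": hard,
            "cluster_label": model.cluster_labels[hard],
        }
        if summaries is not None:
            c, med = summaries[i].at_time(endpoint_h)
            row["quadrant_at_endpoint"] = assign_quadrant(c, med, thresholds).value
        rows.append(row)
    return pd.DataFrame(rows)
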