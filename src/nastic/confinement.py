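"""Orthogonal confinement validation via vector autoregression.

Independently of any clustering, each trajectory is summarised by four
numbers: the MSD anomalous exponent alpha, the convex-hull area, and the
Frobenius norms of the coefficient and residual-covariance matrices of a
first-order vector autoregression fitted to the mean-centred 2D position
series (p_i = A·p_{i−1} + e_i). A confined molecule keeps returning toward
its anchor point, so its positions stay strongly dependent on their past
(‖A‖ near √2, the norm of the identity) within a small area, while a free
walker's *positions* mean-centred over a short track decorrelate and cover
more ground. K-means with k = 2 on the standardised features splits the
population; the group with the smaller mean hull area is labelled
"confined". Cross-tabulating these labels against cluster membership tests
whether spatiotemporally clustered trajectories are genuinely confined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .features import TrajFeatures
from .io import Trajectory

CONFINED = "confined"
UNCONFINED = "unconfined"


@dataclass
class ConfinementFeatures:
    traj_id: int
    alpha: float
    hull_area: float  # µm²
    var_coef_norm: float
    var_cov_norm: float
    label: str | None = None


def var_features(trajectory: Trajectory) -> tuple[float, float]:
    """Frobenius norms of the VAR(1) coefficient and residual covariance.

    The 2D position series is mean-centred per trajectory, then
    p_i = A·p_{i−1} + e_i is fitted by least squares. Raises ValueError for
    fewer than 6 detections or a singular design (immobile trajectory).
    """
    if trajectory.n_detections < 6:
        raise ValueError("var_features needs >= 6 detections")
    p = trajectory.xy - trajectory.xy.mean(axis=0)
    if not np.any(p):
        raise ValueError("singular design (immobile trajectory)")
    X, Y = p[:-1], p[1:]
    # minimum-norm least squares tolerates collinear (rank-1) designs such
    # as pure drift, where the residuals are still well defined
    A = np.linalg.lstsq(X, Y, rcond=None)[0].T  # Y ≈ X A^T
    resid = Y - X @ A.T
    cov = np.cov(resid, rowvar=False)
    return float(np.linalg.norm(A, "fro")), float(np.linalg.norm(cov, "fro"))


def confinement_features(
    trajectories: Sequence[Trajectory], features: dict[int, TrajFeatures]
) -> tuple[list[ConfinementFeatures], list[int]]:
    """The 4-feature vector per trajectory; returns (features, skipped ids).

    Trajectories with undefined alpha or a singular VAR design are skipped
    and reported, never silently dropped.
    """
    out: list[ConfinementFeatures] = []
    skipped: list[int] = []
    for tr in trajectories:
        f = features[tr.traj_id]
        try:
            coef_norm, cov_norm = var_features(tr)
        except ValueError:
            skipped.append(tr.traj_id)
            continue
        if math.isnan(f.alpha):
            skipped.append(tr.traj_id)
            continue
        out.append(
            ConfinementFeatures(tr.traj_id, f.alpha, f.hull_area, coef_norm, cov_norm)
        )
    return out, skipped


def kmeans_confinement(
    feats: Sequence[ConfinementFeatures], seed: int = 0
) -> dict[int, str]:
    """Two-group K-means on the standardised 4D features.

    Features are z-scored per dimension (without it the µm²-scale hull area
    would dominate). The group with the smaller mean hull area is labelled
    confined. Labels are written back onto the feature objects and returned
    as a traj_id → label mapping.
    """
    if len(feats) < 2:
        raise ValueError("need >= 2 trajectories with complete features")
    X = np.array(
        [[f.alpha, f.hull_area, f.var_coef_norm, f.var_cov_norm] for f in feats]
    )
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all feature vectors identical; no separation possible")
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    areas = [X[km.labels_ == g, 1].mean() for g in (0, 1)]
    confined_group = int(np.argmin(areas))
    labels: dict[int, str] = {}
    for f, g in zip(feats, km.labels_):
        f.label = CONFINED if g == confined_group else UNCONFINED
        labels[f.traj_id] = f.label
    return labels


def confinement_crosstab(
    cluster_labels: dict[int, int | None], var_labels: dict[int, str]
) -> dict[str, float]:
    """2×2 table of clustered/unclustered × confined/unconfined.

    Both labelings must cover the same trajectories. Returns the four
    counts plus derived percentages (of clustered that are confined, and of
    unclustered that are unconfined).
    """
    if set(cluster_labels) != set(var_labels):
        raise ValueError("cluster and confinement labels cover different trajectories")
    n_cc = n_cu = n_uc = n_uu = 0
    for tid, cl in cluster_labels.items():
        clustered = cl is not None
        confined = var_labels[tid] == CONFINED
        if clustered and confined:
            n_cc += 1
        elif clustered:
            n_cu += 1
        elif confined:
            n_uc += 1
        else:
            n_uu += 1
    n_clustered = n_cc + n_cu
    n_unclustered = n_uc + n_uu
    return {
        "clustered_confined": n_cc,
        "clustered_unconfined": n_cu,
        "unclustered_confined": n_uc,
        "unclustered_unconfined": n_uu,
        "pct_clustered_confined": 100.0 * n_cc / n_clustered if n_clustered else float("nan"),
        "pct_unclustered_unconfined": 100.0 * n_uu / n_unclustered if n_unclustered else float("nan"),
    }
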