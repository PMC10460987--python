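"""CSF amyloid-quartile centroids and correlation-based risk-group assignment.

The discovery cohort is split into quartiles of CSF amyloid-beta (lowest
quartile = highest risk, H; highest = lowest risk, L). Within each quartile
the Z-scored regional volumes are averaged to form a centroid profile; any
subject (discovery or external) is then assigned the risk group whose
centroid has the highest Spearman correlation with their own Z-profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("H", "IH", "IL", "L")


def abeta_quartiles(abeta: pd.Series | np.ndarray) -> pd.Series:
    """Label subjects H/IH/IL/L by amyloid quartile (lowest quartile = H).

    Cut points are the 25/50/75 linear-interpolation percentiles of the
    non-missing values; bins above H are left-open/right-closed. Missing
    values receive a missing label.
    """
    values = pd.Series(abeta).astype(float)
    obs = values.dropna()
    if len(obs) < 4:
        raise ValueError("need at least 4 non-missing amyloid values")
    q1, q2, q3 = np.percentile(obs, [25, 50, 75])
    if q1 == q3:
        raise ValueError("degenerate amyloid quartiles (constant values)")
    labels = pd.Series(pd.NA, index=values.index, dtype="object")
    labels[values <= q1] = "H"
    labels[(values > q1) & (values <= q2)] = "IH"
    labels[(values > q2) & (values <= q3)] = "IL"
    labels[values > q3] = "L"
    return labels


@dataclass(frozen=True)
class RiskCentroids:
    """4 x R matrix of group-mean Z-scored volumes (rows H, IH, IL, L)."""

    profiles: pd.DataFrame  # index = GROUPS, columns = regions
    cohort: str = "unnamed"
    group_sizes: dict | None = None

    def __post_init__(self) -> None:
        if list(self.profiles.index) != list(GROUPS):
            raise ValueError(f"centroid rows must be ordered {GROUPS}")
        if not np.isfinite(self.profiles.to_numpy(dtype=float)).all():
            raise ValueError("centroid profiles must be finite")

    def to_csv(self, path) -> None:
        self.profiles.to_csv(path, index_label="group")

    @classmethod
    def from_csv(cls, path, cohort: str = "unnamed") -> "RiskCentroids":
        profiles = pd.read_csv(path, index_col="group")
        return cls(profiles=profiles, cohort=cohort)


def compute_centroids(
    z_table: pd.DataFrame, labels: pd.Series, cohort: str = "unnamed"
) -> RiskCentroids:
    """Average Z-profiles within each amyloid-quartile risk group."""
    labels = labels.reindex(z_table.index)
    if labels.isna().any():
        raise ValueError("every subject in z_table must be labeled")
    rows = {}
    sizes = {}
    for g in GROUPS:
        members = z_table.loc[labels == g]
        if members.empty:
            raise ValueError(f"risk group {g} is empty")
        rows[g] = members.mean(axis=0)
        sizes[g] = len(members)
    profiles = pd.DataFrame(rows).T.loc[list(GROUPS)]
    return RiskCentroids(profiles=profiles, cohort=cohort, group_sizes=sizes)


def assign_risk_groups(
    z_table: pd.DataFrame, centroids: RiskCentroids
) -> pd.DataFrame:
    """Assign each subject the centroid with the highest Spearman correlation.

    Returns a frame indexed like ``z_table`` with columns ``group``,
    ``rho_H .. rho_L`` and ``tie`` (true when the maximum was shared; ties
    are broken toward the higher-risk group).
    """
    if list(z_table.columns) != list(centroids.profiles.columns):
        raise ValueError("feature spaces of subjects and centroids differ")
    if z_table.shape[1] < 3:
        raise ValueError("need at least 3 regions for rank correlation")

    cent = centroids.profiles.to_numpy(dtype=float)
    cent_ranks = stats.rankdata(cent, axis=1)
    cent_ranks -= cent_ranks.mean(axis=1, keepdims=True)
    cent_norm = np.linalg.norm(cent_ranks, axis=1)

    z = z_table.to_numpy(dtype=float)
    if (z.std(axis=1) == 0).any():
        raise ValueError("zero-variance subject profile: ranks undefined")
    z_ranks = stats.rankdata(z, axis=1)
    z_ranks -= z_ranks.mean(axis=1, keepdims=True)
    z_norm = np.linalg.norm(z_ranks, axis=1)

    # Spearman rho = Pearson correlation of (average) ranks
    rho = (z_ranks @ cent_ranks.T) / np.outer(z_norm, cent_norm)
    best = rho.max(axis=1, keepdims=True)
    is_max = np.isclose(rho, best, rtol=0.0, atol=1e-12)
    assigned = is_max.argmax(axis=1)  # first maximum = highest-risk group
    tie = is_max.sum(axis=1) > 1

    out = pd.DataFrame(index=z_table.index)
    out["group"] = [GROUPS[i] for i in assigned]
    for g, name in enumerate(GROUPS):
        out[f"rho_{name}"] = rho[:, g]
    out["tie"] = tie
    return out


def assignment_accuracy(assignment: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of subjects whose assigned group matches the ground truth."""
    merged = assignment.join(truth.set_index("subject_id")["true_group"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping subjects between assignment and truth")
    return float((merged["group"] == merged["true_group"]).mean())
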