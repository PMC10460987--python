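"""Volumetric feature preparation.

Transforms raw atlas-parcellated gray-matter volumes (mm^3, one value per
hemisphere and region) into the model-ready feature space used throughout the
pipeline:

* normalization to total intracranial volume (TIV),
* averaging of paired left/right regions (midline structures pass through),
* removal of ventricular / CSF regions,
* Z-scoring against a fixed discovery-cohort reference,
* aggregation of regional values into anatomical lobes.

The region catalog shipped with the package (``data/region_catalog.csv``)
defines region names, hemisphere pairing, lobe membership and the reference
mean/SD of each region's normalized volume. The mesial temporal lobe is, by
definition, exactly the entorhinal area, parahippocampal gyrus, hippocampus
and amygdala.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MESIAL_TEMPORAL_REGIONS = frozenset(
    {"Entorhinal area", "Parahippocampal gyrus", "Hippocampus", "Amygdala"}
)

LOBES = (
    "frontal",
    "parietal",
    "occipital",
    "mesial temporal",
    "other temporal",
    "cingulate",
    "insula",
    "basal ganglia",
    "subcortical",
    "ventricle/CSF",
)


@dataclass(frozen=True)
class RegionCatalog:
    """Atlas region catalog.

    ``table`` has one row per hemispheric region with columns
    ``region`` (merged name), ``hemisphere`` (left/right/none), ``lobe``,
    ``ref_mean`` and ``ref_sd`` (reference normalized-volume statistics).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.table["lobe"]) - set(LOBES)
        if bad:
            raise ValueError(f"unknown lobes in catalog: {sorted(bad)}")
        mt = set(self.table.loc[self.table["lobe"] == "mesial temporal", "region"])
        if mt != set(MESIAL_TEMPORAL_REGIONS):
            raise ValueError(
                "mesial temporal lobe must contain exactly the entorhinal area, "
                f"parahippocampal gyrus, hippocampus and amygdala; got {sorted(mt)}"
            )

    @property
    def merged_regions(self) -> list[str]:
        """Merged (hemisphere-averaged) region names, catalog order."""
        return list(dict.fromkeys(self.table["region"]))

    @property
    def gray_matter_regions(self) -> list[str]:
        return [r for r in self.merged_regions if r not in self.ventricle_regions]

    @property
    def ventricle_regions(self) -> list[str]:
        vent = self.table.loc[self.table["lobe"] == "ventricle/CSF", "region"]
        return list(dict.fromkeys(vent))

    def lobe_of(self, region: str) -> str:
        hit = self.table.loc[self.table["region"] == region, "lobe"]
        if hit.empty:
            raise KeyError(f"region not in catalog: {region}")
        return hit.iloc[0]

    def lobe_members(self, lobe: str) -> list[str]:
        members = self.table.loc[self.table["lobe"] == lobe, "region"]
        return list(dict.fromkeys(members))

    def is_paired(self, region: str) -> bool:
        hemis = set(self.table.loc[self.table["region"] == region, "hemisphere"])
        return hemis == {"left", "right"}

    def reference(self, regions: list[str] | None = None) -> "ZScoreReference":
        """Packaged per-region reference (mean, SD) of normalized volume."""
        regions = regions if regions is not None else self.gray_matter_regions
        sub = self.table.drop_duplicates("region").set_index("region")
        means = {r: float(sub.loc[r, "ref_mean"]) for r in regions}
        sds = {r: float(sub.loc[r, "ref_sd"]) for r in regions}
        return ZScoreReference(means=means, sds=sds, cohort="packaged-reference")


def load_catalog(path: str | Path | None = None) -> RegionCatalog:
    """Load the packaged region catalog, or a user-supplied CSV."""
    if path is None:
        with resources.files("mcisurv.data").joinpath("region_catalog.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return RegionCatalog(table=table)


@dataclass(frozen=True)
class ZScoreReference:
    """Per-region mean/SD of normalized volume from a named discovery cohort."""

    means: dict[str, float]
    sds: dict[str, float]
    cohort: str = "unnamed"

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise ValueError("mean and SD region sets differ")
        bad = [r for r, s in self.sds.items() if not s > 0]
        if bad:
            raise ValueError(f"non-positive SD for regions: {bad}")

    @property
    def regions(self) -> list[str]:
        return list(self.means)

    def to_json(self, path: str | Path) -> None:
        payload = {"cohort": self.cohort, "means": self.means, "sds": self.sds}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ZScoreReference":
        payload = json.loads(Path(path).read_text())
        return cls(means=payload["means"], sds=payload["sds"], cohort=payload.get("cohort", "unnamed"))

    @classmethod
    def estimate(cls, table: pd.DataFrame, cohort: str = "estimated") -> "ZScoreReference":
        """Estimate a reference from a table of normalized volumes (rows = subjects)."""
        means = table.mean(axis=0)
        sds = table.std(axis=0, ddof=1)
        return cls(means=means.to_dict(), sds=sds.to_dict(), cohort=cohort)


def normalize_and_average(
    raw: pd.DataFrame, tiv: pd.Series, catalog: RegionCatalog
) -> pd.DataFrame:
    """TIV-normalize raw volumes and average paired hemispheres.

    ``raw`` columns are ``"<region> (left)"`` / ``"<region> (right)"`` for
    paired regions and the bare region name for midline structures; values in
    mm^3. Output columns are merged region names; values are fractions of TIV
    (mean of the two hemispheres for paired regions).
    """
    tiv = pd.Series(tiv, index=raw.index, dtype=float)
    if (tiv <= 0).any():
        raise ValueError("tiv must be positive for every subject")
    if (raw.to_numpy(dtype=float) < 0).any():
        raise ValueError("raw volumes must be non-negative")
    out = {}
    for region in catalog.merged_regions:
        if catalog.is_paired(region):
            left, right = f"{region} (left)", f"{region} (right)"
            missing = [c for c in (left, right) if c not in raw.columns]
            if missing:
                raise KeyError(f"missing hemisphere columns: {missing}")
            out[region] = (raw[left] + raw[right]) / 2.0 / tiv
        else:
            if region not in raw.columns:
                raise KeyError(f"missing midline column: {region}")
            out[region] = raw[region] / tiv
    return pd.DataFrame(out, index=raw.index)


def drop_ventricles(table: pd.DataFrame, catalog: RegionCatalog) -> pd.DataFrame:
    """Remove ventricular/CSF region columns; all other columns untouched."""
    vents = [r for r in catalog.ventricle_regions if r in table.columns]
    if not vents:
        logger.info("no ventricular regions present; table unchanged")
        return table.copy()
    logger.info("dropping %d ventricular regions: %s", len(vents), vents)
    return table.drop(columns=vents)


def zscore_to_reference(table: pd.DataFrame, ref: ZScoreReference) -> pd.DataFrame:
    """Z-score each region column against the reference mean/SD."""
    missing = [r for r in table.columns if r not in ref.means]
    if missing:
        raise KeyError(f"regions absent from reference: {missing}")
    means = np.array([ref.means[r] for r in table.columns])
    sds = np.array([ref.sds[r] for r in table.columns])
    return (table - means) / sds


def inverse_zscore(z_table: pd.DataFrame, ref: ZScoreReference) -> pd.DataFrame:
    """Invert :func:`zscore_to_reference` (z * SD + mean)."""
    means = np.array([ref.means[r] for r in z_table.columns])
    sds = np.array([ref.sds[r] for r in z_table.columns])
    return z_table * sds + means


def aggregate_lobes(
    values: pd.DataFrame | pd.Series, catalog: RegionCatalog
) -> pd.DataFrame | pd.Series:
    """Unweighted mean of region values within each lobe.

    Accepts a Series (one subject) or DataFrame (rows = subjects) whose
    index/columns are merged region names. Only lobes with at least one
    region present contribute; a fully absent lobe is skipped, but a lobe
    explicitly requested via the catalog with zero members raises.
    """
    frame = values.to_frame().T if isinstance(values, pd.Series) else values
    unknown = [r for r in frame.columns if r not in catalog.merged_regions]
    if unknown:
        raise KeyError(f"regions not in catalog: {unknown}")
    out = {}
    for lobe in LOBES:
        members = [r for r in catalog.lobe_members(lobe) if r in frame.columns]
        if members:
            out[lobe] = frame[members].mean(axis=1)
    result = pd.DataFrame(out, index=frame.index)
    return result.iloc[0] if isinstance(values, pd.Series) else result
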