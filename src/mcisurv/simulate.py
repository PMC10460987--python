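"""Synthetic cohort generator.

Produces subject-level tables (regional gray-matter volume fractions, CSF
amyloid-beta, right-censored time to AD conversion) and, optionally, small 3D
brain-like volumes, with the statistical structure the downstream analysis
assumes:

* four latent risk groups H > IH > IL > L tied to disjoint CSF amyloid ranges
  (lower amyloid = higher risk),
* group-dependent regional atrophy expressed as mean Z-shifts of normalized
  volumes, most severe in the mesial temporal regions for the high-risk
  groups and mild, frontal-predominant (aging-like) in the low-risk group,
* conversion times drawn from a discrete piecewise-constant hazard over the
  bins [0,24), [24,48), [48,108) months (sequential Bernoulli per bin,
  uniform placement within the chosen bin),
* independent uniform censoring calibrated to a target marginal censoring
  fraction, plus administrative censoring at 108 months.

A ground-truth table (latent group, hazards, latent event and censor times)
accompanies every cohort so that recovery tests can score the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volumetrics import RegionCatalog, ZScoreReference, load_catalog

logger = logging.getLogger(__name__)

GROUPS = ("H", "IH", "IL", "L")
BIN_EDGES = (0.0, 24.0, 48.0, 108.0)

#: Discovery-cohort group sizes n_H=139, n_IH=105, n_IL=90, n_L=206,
#: normalized over their total (540) to proper proportions.
DEFAULT_GROUP_FRACTIONS = (139 / 540, 105 / 540, 90 / 540, 206 / 540)

#: Disjoint amyloid (pg/mL) ranges per group, within the assay limits
#: [200, 1700]; the H group occupies the lowest amyloid range.
DEFAULT_ABETA_RANGES = (
    (200.0, 575.0),
    (575.0, 950.0),
    (950.0, 1325.0),
    (1325.0, 1700.0),
)

#: Per-bin conditional conversion probabilities per group (rows H..L).
DEFAULT_BIN_HAZARDS = (
    (0.30, 0.28, 0.32),
    (0.20, 0.20, 0.25),
    (0.12, 0.15, 0.20),
    (0.05, 0.08, 0.12),
)

#: Mean atrophy (Z-shift of normalized volume) per lobe and group. High-risk
#: groups show the AD gradient (mesial temporal worst, spreading outward);
#: the low-risk group shows mild frontal-predominant, aging-like change.
DEFAULT_LOBE_ATROPHY = {
    "H": {
        "mesial temporal": -2.4, "other temporal": -1.6, "parietal": -1.2,
        "cingulate": -0.9, "frontal": -0.7, "insula": -0.7, "occipital": -0.5,
        "basal ganglia": -0.35, "subcortical": -0.25,
    },
    "IH": {
        "mesial temporal": -1.5, "other temporal": -0.9, "parietal": -0.6,
        "cingulate": -0.35, "frontal": -0.45, "insula": -0.3, "occipital": -0.1,
        "basal ganglia": -0.1, "subcortical": -0.05,
    },
    "IL": {
        "mesial temporal": -0.9, "other temporal": -0.45, "parietal": -0.25,
        "cingulate": -0.15, "frontal": -0.5, "insula": -0.15, "occipital": -0.05,
        "basal ganglia": -0.35, "subcortical": -0.05,
    },
    "L": {
        "mesial temporal": -0.15, "other temporal": -0.05, "parietal": -0.05,
        "cingulate": -0.05, "frontal": -0.45, "insula": -0.05, "occipital": 0.0,
        "basal ganglia": -0.3, "subcortical": 0.0,
    },
}

#: Relative amplitude of the fixed per-region vulnerability jitter that makes
#: each group's regional pattern distinctive beyond its lobe-level profile.
REGION_JITTER = 0.5
_JITTER_SEED = 20230802  # fixed: the jitter is part of the generator, not a dial


def default_atrophy_means(catalog: RegionCatalog | None = None) -> np.ndarray:
    """Default 4 x n_regions matrix of mean Z-shifts (rows H, IH, IL, L).

    Lobe-level severities from :data:`DEFAULT_LOBE_ATROPHY` modulated by a
    fixed per-group, per-region vulnerability jitter (regional vulnerability
    differs idiosyncratically between strata). Deterministic.
    """
    catalog = catalog or load_catalog()
    regions = catalog.gray_matter_regions
    rng = np.random.default_rng(_JITTER_SEED)
    jitter = rng.uniform(-1.0, 1.0, size=(len(GROUPS), len(regions)))
    means = np.zeros((len(GROUPS), len(regions)))
    for g, group in enumerate(GROUPS):
        for r, region in enumerate(regions):
            base = DEFAULT_LOBE_ATROPHY[group][catalog.lobe_of(region)]
            means[g, r] = base * (1.0 + REGION_JITTER * jitter[g, r])
    return means


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort draw."""

    n_subjects: int
    seed: int = 0
    n_regions: int = 66
    group_fractions: tuple = DEFAULT_GROUP_FRACTIONS
    abeta_ranges: tuple = DEFAULT_ABETA_RANGES
    atrophy_means: np.ndarray | None = None  # 4 x n_regions; default built from catalog
    noise_sd: float = 0.5
    bin_hazards: tuple = DEFAULT_BIN_HAZARDS
    censor_rate: float = 0.72
    admin_cap_months: float = 108.0
    cohort_label: str = "synthetic"

    def validate(self, catalog: RegionCatalog) -> np.ndarray:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        fr = np.asarray(self.group_fractions, dtype=float)
        if fr.shape != (4,) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("group_fractions must be 4 proportions summing to 1")
        hz = np.asarray(self.bin_hazards, dtype=float)
        if hz.shape != (4, 3) or (hz < 0).any() or (hz > 1).any():
            raise ValueError("bin_hazards must be a 4x3 matrix of probabilities")
        for lo, hi in self.abeta_ranges:
            if not (200.0 <= lo < hi <= 1700.0):
                raise ValueError("abeta_ranges must be ordered within [200, 1700]")
        los = [lo for lo, _ in self.abeta_ranges]
        if los != sorted(los):
            raise ValueError("abeta_ranges must ascend from H (lowest) to L (highest)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        means = (
            np.asarray(self.atrophy_means, dtype=float)
            if self.atrophy_means is not None
            else default_atrophy_means(catalog)
        )
        if means.shape != (4, self.n_regions):
            raise ValueError(f"atrophy_means must be 4 x {self.n_regions}")
        return means


def _event_probabilities(bin_hazards: np.ndarray) -> np.ndarray:
    """P(conversion in bin j) per group: h_j * prod_{i<j}(1 - h_i)."""
    surv = np.cumprod(1.0 - bin_hazards, axis=1)
    prev = np.concatenate([np.ones((bin_hazards.shape[0], 1)), surv[:, :-1]], axis=1)
    return bin_hazards * prev


def _calibrate_censor_prob(
    fractions: np.ndarray, bin_hazards: np.ndarray, censor_rate: float, cap: float
) -> float:
    """Probability q of drawing an early uniform censor time so that the
    marginal censoring fraction matches ``censor_rate``.

    P(censored) = P(no conversion) + q * E[T/cap ; T finite]: a uniform
    censor time on (0, cap] precedes a conversion at t with probability t/cap.
    """
    pj = _event_probabilities(bin_hazards)  # 4 x 3
    p_none = 1.0 - pj.sum(axis=1)  # per group
    mids = np.array([(BIN_EDGES[j] + BIN_EDGES[j + 1]) / 2 for j in range(3)])
    e_t_frac = (pj * mids).sum(axis=1) / cap  # E[T/cap ; finite] per group
    base = float(fractions @ p_none)
    slope = float(fractions @ e_t_frac)
    if censor_rate <= base or slope == 0.0:
        if 0.0 < censor_rate < base - 1e-9:
            logger.warning(
                "target censor_rate %.3f below administrative floor %.3f; using q=0",
                censor_rate, base,
            )
        return 0.0
    return float(np.clip((censor_rate - base) / slope, 0.0, 1.0))


def simulate_cohort(
    config: SimulationConfig, catalog: RegionCatalog | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and its ground-truth table.

    Returns ``(cohort, truth)``. ``cohort`` columns: subject_id, cohort,
    abeta, time_months, event, then one column per gray-matter region
    (volume as a fraction of intracranial volume). ``truth`` columns:
    subject_id, true_group, h1..h3, latent_event_time (inf for
    non-converters), censor_time.
    """
    catalog = catalog or load_catalog()
    means = config.validate(catalog)
    regions = catalog.gray_matter_regions[: config.n_regions]
    if len(regions) < config.n_regions:
        raise ValueError("catalog has fewer gray-matter regions than n_regions")
    ref = catalog.reference(regions)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    fr = np.asarray(config.group_fractions, dtype=float)
    hz = np.asarray(config.bin_hazards, dtype=float)

    group_idx = rng.choice(4, size=n, p=fr)
    abeta = np.empty(n)
    for g, (lo, hi) in enumerate(config.abeta_ranges):
        mask = group_idx == g
        abeta[mask] = rng.uniform(lo, hi, size=mask.sum())

    z = means[group_idx] + rng.normal(0.0, config.noise_sd, size=(n, len(regions)))
    mu = np.array([ref.means[r] for r in regions])
    sd = np.array([ref.sds[r] for r in regions])
    volumes = np.clip(mu + z * sd, 0.0, None)

    # conversion times: sequential Bernoulli over bins, uniform inside the bin
    latent = np.full(n, np.inf)
    u_bin = rng.random((n, 3))
    u_pos = rng.random((n, 3))
    # sequential Bernoulli: the first bin whose draw fires is the event bin
    fires = u_bin < hz[group_idx]  # n x 3
    any_fire = fires.any(axis=1)
    first = np.where(any_fire, fires.argmax(axis=1), -1)
    for j in range(3):
        sel = first == j
        lo, hi = BIN_EDGES[j], BIN_EDGES[j + 1]
        latent[sel] = lo + (hi - lo) * u_pos[sel, j]
    latent = np.where(latent == 0.0, 1e-9, latent)  # conversion strictly after entry

    q = _calibrate_censor_prob(fr, hz, config.censor_rate, config.admin_cap_months)
    early = rng.random(n) < q
    censor = np.where(
        early, rng.uniform(0.0, config.admin_cap_months, n), config.admin_cap_months
    )
    time_obs = np.minimum(latent, censor)
    event = latent <= censor

    ids = [f"{config.cohort_label}-{i:05d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "subject_id": ids,
            "cohort": config.cohort_label,
            "abeta": abeta,
            "time_months": time_obs,
            "event": event,
        }
    )
    for r, region in enumerate(regions):
        cohort[region] = volumes[:, r]
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "true_group": [GROUPS[g] for g in group_idx],
            "h1": hz[group_idx, 0],
            "h2": hz[group_idx, 1],
            "h3": hz[group_idx, 2],
            "latent_event_time": latent,
            "censor_time": censor,
        }
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# 3D volume images


@dataclass(frozen=True)
class ImageConfig:
    """Desk-scale stand-in for a normalized, bias-corrected T1 volume."""

    shape: tuple = (32, 32, 32)
    baseline: float = 1.0
    effect_scale: float = 0.25
    noise_sd: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class VolumeImage:
    """A 3D intensity volume with its brain mask and region id map."""

    voxels: np.ndarray
    mask: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.voxels).all():
            raise ValueError("intensities must be finite")
        if not self.mask[self.region_ids > 0].all():
            raise ValueError("mask must be true wherever region id > 0")


def make_region_layout(shape: tuple, n_regions: int) -> np.ndarray:
    """Fixed layout of ``n_regions`` non-overlapping ellipsoids in the grid.

    Regions occupy cells of a regular lattice; ids are 1..n_regions in
    catalog order, 0 is background. Raises if the grid is too small for
    every ellipsoid to span at least 3 voxels per axis.
    """
    shape = tuple(shape)
    k = 1
    while True:
        dims = _lattice_dims(n_regions, k)
        if np.prod(dims) >= n_regions:
            break
        k += 1
    cells = [s // d for s, d in zip(shape, dims)]
    if min(cells) < 4:
        raise ValueError(f"grid {shape} too small for {n_regions} regions")
    region_ids = np.zeros(shape, dtype=np.int32)
    coords = np.indices(shape)
    rid = 1
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                if rid > n_regions:
                    break
                center = [
                    (i + 0.5) * c for i, c in zip((ix, iy, iz), cells)
                ]
                radii = [0.42 * c for c in cells]
                d2 = sum(
                    ((coords[a] - center[a]) / radii[a]) ** 2 for a in range(3)
                )
                region_ids[d2 <= 1.0] = rid
                rid += 1
    return region_ids


def _lattice_dims(n_regions: int, extra: int) -> tuple:
    side = int(np.ceil(n_regions ** (1 / 3)))
    dims = [side, side, side]
    i = 0
    while np.prod(dims) < n_regions:
        dims[i % 3] += 1
        i += 1
    return tuple(dims)


def simulate_images(
    cohort: pd.DataFrame,
    z_table: pd.DataFrame,
    img_config: ImageConfig,
) -> list[VolumeImage]:
    """Render one synthetic volume per subject.

    Voxel intensity inside region r is ``baseline * (1 + effect_scale * z_r)``
    plus Gaussian noise; background is 0. The region id map is shared across
    subjects. Negative intensities are clipped at 0 (counted and logged).
    """
    n_regions = z_table.shape[1]
    region_ids = make_region_layout(img_config.shape, n_regions)
    rng = np.random.default_rng(img_config.seed)
    mask = region_ids > 0
    images = []
    n_clipped = 0
    z = z_table.to_numpy(dtype=float)
    for i in range(len(cohort)):
        vox = np.zeros(img_config.shape, dtype=np.float32)
        for r in range(n_regions):
            sel = region_ids == (r + 1)
            vox[sel] = img_config.baseline * (1.0 + img_config.effect_scale * z[i, r])
        if img_config.noise_sd > 0:
            vox[mask] += rng.normal(0.0, img_config.noise_sd, size=int(mask.sum()))
        neg = vox < 0
        n_clipped += int(neg.sum())
        vox[neg] = 0.0
        images.append(VolumeImage(voxels=vox, mask=mask, region_ids=region_ids))
    if n_clipped:
        logger.info("clipped %d negative voxels across %d images", n_clipped, len(images))
    return images


def split_folds(
    n: int, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """k-fold partitions in a train:val:test = (k-2):1:1 fashion.

    Each fold takes one shuffled k-th of the subjects as test, the next as
    validation and the remainder as training; the test sets tile the cohort.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = np.array_split(perm, k)
    folds = []
    for i in range(k):
        test = parts[i]
        val = parts[(i + 1) % k]
        train = np.concatenate([parts[j] for j in range(k) if j not in (i, (i + 1) % k)])
        folds.append((np.sort(train), np.sort(val), np.sort(test)))
    return folds
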