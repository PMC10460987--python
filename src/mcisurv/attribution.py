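"""Voxelwise attribution of the convolutional survival model.

Additive attributions are computed by integrated gradients along the
straight path from each background sample to the input, averaged over the
background set. The survival networks are a smooth sigmoid applied to a
piecewise-linear map g, so the path integral is evaluated segment-wise:
within each path interval the pre-sigmoid input gradient is taken at the
midpoint and the interval's contribution is normalized by the exact change
of the sigmoid output across the interval (a rescale in the spirit of
DeepLIFT). Because the per-voxel contributions of an interval sum to that
exact output change, the completeness identity — voxel attributions for
output bin j sum to f_j(x) - mean_b f_j(b) — holds by construction, not
merely in the many-steps limit; the step count only controls how finely
the attribution is resolved spatially.

Downstream aggregation follows the study design: absolute values averaged
over output bins (and cross-validation folds) per subject, group-mean
difference maps Z-scored across in-mask voxels and thresholded, and mean
absolute attribution per anatomical region with pairwise signed-rank tests.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .classical import bh_adjust
from .nets import Network

logger = logging.getLogger(__name__)


def _split_head(network: Network):
    """Split the network into (piecewise-linear body, smooth output map).

    A final sigmoid is treated analytically; any other tail means the whole
    network is the body and the output map is the identity.
    """
    from scipy.special import expit

    from .nets import Sigmoid

    if isinstance(network.layers[-1], Sigmoid):
        return network.layers[:-1], expit
    return network.layers, lambda g: g


def _forward_layers(layers, x: np.ndarray, rng) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, False, rng)
    return x


def _backward_layers(layers, grad: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        grad = layer.backward(grad, need_param_grads=False)
    return grad


def compute_attributions(
    network: Network,
    images: np.ndarray,
    background: np.ndarray,
    steps: int = 16,
) -> np.ndarray:
    """Path-integrated attributions per subject and output bin.

    ``images``: (n, 1, D, H, W); ``background``: (m, 1, D, H, W) — the small
    training subset whose mean output is the attribution baseline. Returns
    an array (n, n_bins, D, H, W) whose voxel sums reproduce
    f(x) - mean_b f(b) exactly (see module docstring).
    """
    images = np.asarray(images, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != images.ndim or background.shape[1:] != images.shape[1:]:
        raise ValueError("background and images must share the volume shape")
    if len(background) == 0:
        raise ValueError("background set is empty")
    body, head = _split_head(network)
    m = len(background)
    vol_shape = images.shape[1:]
    n_bins = network.forward(background[:1], train=False).shape[1]
    nodes = np.arange(steps + 1) / steps
    mids = (np.arange(steps) + 0.5) / steps
    out = np.zeros((len(images), n_bins) + images.shape[2:])
    for i, x in enumerate(images):
        diffs = x[None] - background  # (m, 1, D, H, W)
        node_pts = (
            background[:, None] + nodes[None, :, None, None, None, None] * diffs[:, None]
        ).reshape((m * (steps + 1),) + vol_shape)
        g_nodes = _forward_layers(body, node_pts, network.rng).reshape(m, steps + 1, n_bins)
        delta_out = np.diff(head(g_nodes), axis=1)  # (m, steps, n_bins)
        mid_pts = (
            background[:, None] + mids[None, :, None, None, None, None] * diffs[:, None]
        ).reshape((m * steps,) + vol_shape)
        _forward_layers(body, mid_pts, network.rng)
        for j in range(n_bins):
            seed = np.zeros((m * steps, n_bins))
            seed[:, j] = 1.0
            grad = _backward_layers(body, seed)  # d g_j / d input at midpoints
            grad = grad.reshape((m, steps) + vol_shape)
            contrib = grad * diffs[:, None]      # (m, steps, 1, D, H, W)
            # slope of g_j along the path at each interval midpoint
            slope = contrib.reshape(m, steps, -1).sum(axis=2)
            safe = np.abs(slope) > 1e-12
            # normalize each interval so its voxel sum equals the exact
            # head-output change across the interval: completeness holds by
            # construction, the step count only sharpens spatial resolution
            ratio = np.where(safe, delta_out[:, :, j] / np.where(safe, slope, 1.0), 0.0)
            out[i, j] = (
                (contrib * ratio[:, :, None, None, None, None]).sum(axis=1).mean(axis=0)[0]
            )
    return out


def completeness_gap(
    network: Network, images: np.ndarray, background: np.ndarray,
    attributions: np.ndarray,
) -> np.ndarray:
    """Relative completeness error per subject and bin.

    |sum(attr) - (f(x) - mean_b f(b))| / max(|f(x) - mean_b f(b)|, 1e-8).
    """
    fx = network.forward(np.asarray(images, dtype=float), train=False)
    fb = network.forward(np.asarray(background, dtype=float), train=False).mean(axis=0)
    target = fx - fb
    total = attributions.reshape(attributions.shape[0], attributions.shape[1], -1).sum(axis=2)
    return np.abs(total - target) / np.maximum(np.abs(target), 1e-8)


def aggregate_subject_maps(maps: np.ndarray) -> np.ndarray:
    """Elementwise mean of absolute values across bins (and folds).

    ``maps``: (..., n_subjects, D, H, W) with any number of leading
    aggregation axes (bins, folds). Returns (n_subjects, D, H, W).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim < 4:
        raise ValueError("expected at least (subjects, D, H, W)")
    lead = maps.ndim - 4
    return np.abs(maps).mean(axis=tuple(range(lead))) if lead else np.abs(maps)


def group_difference_zmap(
    subject_maps: np.ndarray,
    groups: np.ndarray,
    pair: tuple,
    mask: np.ndarray | None = None,
    threshold: float = 2.5,
) -> np.ndarray:
    """Thresholded Z-map of the higher-risk minus lower-risk mean map.

    Mean maps per group are subtracted (higher - lower), Z-scored with the
    mean/SD over in-mask voxels of the difference map, and voxels with
    |Z| < threshold are set to 0.
    """
    groups = np.asarray(groups)
    higher, lower = pair
    m_high = subject_maps[groups == higher].mean(axis=0)
    m_low = subject_maps[groups == lower].mean(axis=0)
    diff = m_high - m_low
    mask = np.ones(diff.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    vals = diff[mask]
    sd = vals.std()
    if sd == 0.0:
        if np.allclose(vals, 0.0):  # identical group means: nothing to show
            return np.zeros_like(diff)
        raise ValueError("zero across-voxel SD in the difference map")
    z = np.zeros_like(diff)
    z[mask] = (vals - vals.mean()) / sd
    z[np.abs(z) < threshold] = 0.0
    z[~mask] = 0.0
    return z


def region_importance(
    subject_maps: np.ndarray,
    region_ids: np.ndarray,
    region_names: dict,
    groups: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-subject mean absolute attribution per named region.

    Returns ``(importance, tests, summaries)``:

    * importance — one row per subject, one column per region, plus ``group``;
    * tests — within each risk group, every region pair compared with the
      Wilcoxon signed-rank test, Benjamini-Hochberg adjusted per group;
    * summaries — group-level region means with bootstrap 95% intervals.
    """
    groups = np.asarray(groups)
    region_ids = np.asarray(region_ids)
    cols = {}
    for rid, name in region_names.items():
        sel = region_ids == rid
        if not sel.any():
            raise ValueError(f"region {name} (id {rid}) covers no voxels")
        cols[name] = np.abs(subject_maps[:, sel]).mean(axis=1)
    importance = pd.DataFrame(cols)
    importance["group"] = groups

    rows = []
    names = list(region_names.values())
    for g in pd.unique(groups):
        sub = importance.loc[importance["group"] == g, names]
        if len(sub) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects for testing")
        pvals, pairs = [], []
        for a, b in itertools.combinations(names, 2):
            diff = sub[a].to_numpy() - sub[b].to_numpy()
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(sub[a], sub[b]).pvalue)
            pvals.append(p)
            pairs.append((a, b))
        adj = bh_adjust(pvals)
        for (a, b), p, q in zip(pairs, pvals, adj):
            rows.append({"group": g, "region_a": a, "region_b": b,
                         "p": p, "p_bh": float(q)})
    tests = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    srows = []
    for g in pd.unique(groups):
        sub = importance.loc[importance["group"] == g, names].to_numpy()
        idx = rng.integers(0, len(sub), size=(n_boot, len(sub)))
        boot_means = sub[idx].mean(axis=1)
        lo = np.percentile(boot_means, 2.5, axis=0)
        hi = np.percentile(boot_means, 97.5, axis=0)
        for j, name in enumerate(names):
            srows.append({"group": g, "region": name,
                          "mean": float(sub[:, j].mean()),
                          "ci_lower": float(lo[j]), "ci_upper": float(hi[j])})
    summaries = pd.DataFrame(srows)
    return importance, tests, summaries
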