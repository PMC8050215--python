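"""Aggregate per-fold selections into per-feature relevance weights.

A feature's relevance is the hold-out accuracy above empirical chance summed
over every fold whose final selection contained it, normalized so all
weights sum to 100 (percent contribution to overall performance).  HOG
weights project onto the stimulus grid as spatial heatmaps; Fourier weights
marginalize into spatial-frequency and orientation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FourierBinning, HOGSpec

__all__ = [
    "RelevanceWeights",
    "feature_weights",
    "hog_heatmap",
    "sf_orientation_profiles",
    "plot_hog_heatmap",
    "plot_sf_orientation_profiles",
]

logger = logging.getLogger("gazedecode.relevance")


@dataclass
class RelevanceWeights:
    """Non-negative per-feature weights summing to 100 (percent).

    ``flagged_all_zero`` marks the degenerate case of no fold scoring above
    chance; the weights are then all zero rather than normalized.
    """

    weights: np.ndarray
    n_runs: int
    n_folds: int
    flagged_all_zero: bool = False

    def top(self, n: int) -> np.ndarray:
        """Indices of the n largest weights (ties by lower index)."""
        return np.argsort(-self.weights, kind="stable")[:n]


def feature_weights(results, chance, n_features: int = None,
                    per_run_average: bool = False) -> RelevanceWeights:
    """Accuracy-above-chance attribution to selected features.

    For every fold of every run, each feature in the fold's final selection
    accrues ``max(0, holdout_accuracy − chance_mean)``; weights are then
    normalized to sum 100.  Unselected features keep weight 0.

    Parameters
    ----------
    results : DecodingResult or list of DecodingResult
    chance : ChanceEstimate or float
        The empirical chance level to subtract.
    per_run_average : bool
        If True, normalize each run's raw weights before averaging across
        runs (within-run-first aggregation); default sums raw contributions
        over all folds of all runs before normalizing.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    chance_mean = getattr(chance, "mean", chance)
    if n_features is None:
        n_features = results[0].n_features
    if not n_features:
        raise ValueError("feature-space size unknown; pass n_features")

    per_run = []
    n_folds = 0
    for res in results:
        raw = np.zeros(n_features)
        for fr in res.fold_results:
            gain = max(0.0, fr.final_accuracy - chance_mean)
            raw[np.asarray(fr.final, dtype=int)] += gain
            n_folds += 1
        per_run.append(raw)

    if per_run_average:
        normed = [r / r.sum() for r in per_run if r.sum() > 0]
        raw = np.mean(normed, axis=0) if normed else np.zeros(n_features)
    else:
        raw = np.sum(per_run, axis=0)

    total = raw.sum()
    if total <= 0:
        logger.warning("no fold scored above chance; relevance weights are "
                       "all zero")
        return RelevanceWeights(np.zeros(n_features), len(results), n_folds,
                                flagged_all_zero=True)
    return RelevanceWeights(raw / total * 100.0, len(results), n_folds)


def hog_heatmap(weights, spec: HOGSpec) -> np.ndarray:
    """Project HOG relevance onto the stimulus grid.

    Each kept cell's value is the sum of its orientation-bin weights; cells
    outside the aperture are NaN.  In-aperture values sum to the total
    weight (100 for normalized input).
    """
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if len(w) != spec.n_features:
        raise ValueError(f"expected {spec.n_features} HOG weights, got {len(w)}")
    g = spec.grid_size
    heat = np.full((g, g), np.nan)
    per_cell = w.reshape(len(spec.kept_cells), spec.n_orientation_bins).sum(axis=1)
    for (r, c), v in zip(spec.kept_cells, per_cell):
        heat[r, c] = v
    return heat


def sf_orientation_profiles(weights, binning: FourierBinning):
    """Marginal relevance per SF band and per orientation band.

    Both profiles sum to the total weight (100 for normalized input).
    Returns ``(sf_profile, orientation_profile)``.
    """
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if len(w) != binning.n_features:
        raise ValueError(
            f"expected {binning.n_features} Fourier weights, got {len(w)}")
    grid = w.reshape(binning.n_sf_bands, binning.n_orientation_bands)
    return grid.sum(axis=1), grid.sum(axis=0)


# ---------------------------------------------------------------------------
# rendering / export
# ---------------------------------------------------------------------------

def plot_hog_heatmap(weights, spec: HOGSpec, path=None, ax=None):
    """Render the spatial relevance heatmap; optionally save as PNG/CSV."""
    import matplotlib
    import matplotlib.pyplot as plt

    heat = hog_heatmap(weights, spec)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(heat, cmap="viridis")
    ax.set_title(f"HOG relevance ({spec.cell_size_px}px cells, % of performance)")
    ax.set_xlabel("cell column")
    ax.set_ylabel("cell row")
    plt.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        pd.DataFrame(heat).to_csv(str(path) + ".csv", index=False)
    return ax


def plot_sf_orientation_profiles(weights, binning: FourierBinning, path=None):
    """Render SF and orientation relevance profiles; optionally save."""
    import matplotlib.pyplot as plt

    sf, ori = sf_orientation_profiles(weights, binning)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    centers = 0.5 * (np.asarray(binning.sf_band_edges[:-1])
                     + np.asarray(binning.sf_band_edges[1:]))
    ax1.plot(centers, sf, marker="o", ms=3)
    ax1.set_xlabel("spatial frequency (cycles/image)")
    ax1.set_ylabel("weight (%)")
    ax1.set_title("SF relevance")
    edges = binning.orientation_band_edges
    ax2.plot(0.5 * (edges[:-1] + edges[1:]), ori, marker="o", ms=3)
    ax2.set_xlabel("orientation (deg)")
    ax2.set_title("orientation relevance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        pd.DataFrame({"sf_center_cpi": centers, "weight_pct": sf}).to_csv(
            str(path) + ".sf.csv", index=False)
    return fig
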