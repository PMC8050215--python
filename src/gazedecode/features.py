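"""Low-level image feature extraction for face stimuli.

Two complementary descriptions of a grayscale face stimulus are supported:

* **Binned Fourier magnitude features** — the 2-D magnitude spectrum summed
  within spatial-frequency (cycles per image) × orientation bands.  Phase is
  discarded, so these features describe *how much* contrast energy exists at
  each oriented spatial frequency, not where it is in the image.
* **Aperture-masked HOG features** — per-cell histograms of oriented gradients
  restricted to grid cells that lie fully inside the circular stimulus
  aperture.  These are highly spatially specific edge descriptors.

Trials present two faces side by side; the decodable quantity is the
right-minus-left feature difference together with the side that received the
initial eye movement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "StimulusImage",
    "FourierBinning",
    "HOGSpec",
    "FeatureVector",
    "TrialDifference",
    "load_stimulus",
    "fourier_features",
    "aperture_cell_mask",
    "hog_features",
    "trial_difference",
    "feature_matrix",
    "feature_table",
    "geometry_to_json",
]

CANONICAL_WIDTH = 200


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusImage:
    """A square grayscale stimulus inside a circular aperture.

    Parameters
    ----------
    pixels : ndarray
        ``width × width`` float array, intensities in ``[0, 1]``.  Everything
        outside the aperture (the inscribed disc) equals the background value.
    identity : str
        Identity label (e.g. ``"id07"``).
    expression : str
        Expression class label (``happy``/``angry``/``sad``/``neutral`` or a
        synthetic class id).
    """

    pixels: np.ndarray
    identity: str = ""
    expression: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"stimulus must be square, got shape {self.pixels.shape}")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class FourierBinning:
    """Spatial-frequency × orientation binning of the magnitude spectrum.

    The canonical configuration subdivides the spectrum into 24 equal-width
    linear SF bands over ``(0, nyquist]`` cycles per image and 16 orientation
    bands of 11.25° over ``[0°, 180°)``, yielding 384 features.  Frequencies
    above the cardinal-axis Nyquist limit (``width/2`` cpi) and the DC
    component are excluded; the conjugate-symmetric half-plane is counted once.
    """

    n_sf_bands: int = 24
    n_orientation_bands: int = 16
    width_px: int = CANONICAL_WIDTH
    sf_band_edges: tuple = field(default=None)

    def __post_init__(self):
        if self.sf_band_edges is None:
            nyq = self.nyquist_cpi
            edges = tuple(np.linspace(0.0, nyq, self.n_sf_bands + 1))
            object.__setattr__(self, "sf_band_edges", edges)
        edges = np.asarray(self.sf_band_edges)
        if len(edges) != self.n_sf_bands + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("sf_band_edges must be monotone with n_sf_bands+1 entries")

    @property
    def nyquist_cpi(self) -> float:
        return self.width_px / 2

    @property
    def orientation_band_edges(self) -> np.ndarray:
        return np.linspace(0.0, 180.0, self.n_orientation_bands + 1)

    @property
    def n_features(self) -> int:
        return self.n_sf_bands * self.n_orientation_bands

    def feature_names(self) -> list[str]:
        return [
            f"sf{i:02d}_or{j:02d}"
            for i in range(self.n_sf_bands)
            for j in range(self.n_orientation_bands)
        ]


@dataclass(frozen=True)
class HOGSpec:
    """Geometry of the aperture-masked HOG descriptor.

    One unsigned 9-bin orientation histogram per non-overlapping
    ``cell × cell`` px section, restricted to cells fully inside the circular
    aperture.  No block normalization; each cell is L2-normalized on its own.
    """

    cell_size_px: int = 10
    n_orientation_bins: int = 9
    width_px: int = CANONICAL_WIDTH
    aperture_diameter_px: int = None

    def __post_init__(self):
        if self.aperture_diameter_px is None:
            object.__setattr__(self, "aperture_diameter_px", self.width_px)
        if self.width_px % self.cell_size_px != 0:
            raise ValueError(
                f"width {self.width_px} not divisible by cell size {self.cell_size_px}"
            )

    @property
    def grid_size(self) -> int:
        return self.width_px // self.cell_size_px

    @property
    def kept_cells(self) -> list[tuple[int, int]]:
        return aperture_cell_mask(
            self.width_px, self.cell_size_px, aperture_diameter_px=self.aperture_diameter_px
        )

    @property
    def n_features(self) -> int:
        return self.n_orientation_bins * len(self.kept_cells)

    @property
    def n_features_total(self) -> int:
        return self.n_orientation_bins * self.grid_size**2

    def feature_names(self) -> list[str]:
        return [
            f"r{r:02d}c{c:02d}_or{o}"
            for (r, c) in self.kept_cells
            for o in range(self.n_orientation_bins)
        ]


@dataclass
class FeatureVector:
    """Ordered feature values plus the geometry that defines their meaning."""

    values: np.ndarray
    kind: str  # "fourier" | "hog"
    geometry: object

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.values) != self.geometry.n_features:
            raise ValueError(
                f"length {len(self.values)} does not match geometry "
                f"({self.geometry.n_features} features)"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrialDifference:
    """Right-minus-left feature difference with the chosen-side label.

    ``label == 1`` means the right image received the initial eye movement.
    """

    diff: FeatureVector
    label: int
    condition: tuple[str, str] = ("", "")
    soa_ms: int = 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_stimulus(path, identity: str = "", expression: str = "",
                  width_px: int = CANONICAL_WIDTH) -> StimulusImage:
    """Read a grayscale PNG/TIFF, rescale to [0,1] and resample to canonical size.

    Non-canonical sizes are resampled to ``width_px × width_px`` (bilinear)
    before feature extraction so the canonical cell/band geometry applies.
    The background outside the aperture is replaced with the mean in-aperture
    intensity.
    """
    img = Image.open(path).convert("L")
    if img.size != (width_px, width_px):
        img = img.resize((width_px, width_px), Image.BILINEAR)
    px = np.asarray(img, dtype=float) / 255.0
    yy, xx = np.mgrid[0:width_px, 0:width_px]
    c = (width_px - 1) / 2
    inside = (xx - c) ** 2 + (yy - c) ** 2 <= (width_px / 2) ** 2
    px = px.copy()
    px[~inside] = px[inside].mean()
    return StimulusImage(px, identity=identity, expression=expression)


def _spectrum_geometry(binning: FourierBinning):
    """Half-plane frequency coordinates, band indices and keep-mask.

    Returns (sf_band, orient_band, keep) arrays over the full FFT grid where
    ``keep`` selects one representative of each conjugate pair with
    ``0 < r <= nyquist`` (DC excluded).
    """
    w = binning.width_px
    f = np.fft.fftshift(np.fft.fftfreq(w, d=1.0 / w))  # cycles per image
    fx, fy = np.meshgrid(f, f)
    r = np.hypot(fx, fy)
    theta = np.degrees(np.arctan2(fy, fx)) % 180.0

    # one representative per conjugate pair: fy > 0, or fy == 0 and fx > 0
    half = (fy > 0) | ((fy == 0) & (fx > 0))
    keep = half & (r > 0) & (r <= binning.nyquist_cpi)

    edges = np.asarray(binning.sf_band_edges)
    # bands are (lo, hi]; searchsorted with side='left' maps r==edge to the lower band
    sf_band = np.searchsorted(edges, r, side="left") - 1
    orient_band = np.minimum(
        (theta / (180.0 / binning.n_orientation_bands)).astype(int),
        binning.n_orientation_bands - 1,
    )
    return sf_band, orient_band, keep


def fourier_features(img: StimulusImage, binning: FourierBinning = None) -> FeatureVector:
    """Sum the magnitude spectrum within each SF × orientation band.

    The output vector is SF-major then orientation
    (``sf00_or00, sf00_or01, …``).  Bands with no spectrum samples (possible
    at the lowest spatial frequencies for fine orientation binning) are 0.
    """
    if binning is None:
        binning = FourierBinning(width_px=img.width_px)
    if img.width_px != binning.width_px:
        raise ValueError("image width does not match binning geometry")

    mag = np.abs(np.fft.fftshift(np.fft.fft2(img.pixels)))
    sf_band, orient_band, keep = _spectrum_geometry(binning)

    flat_idx = sf_band[keep] * binning.n_orientation_bands + orient_band[keep]
    values = np.bincount(flat_idx, weights=mag[keep], minlength=binning.n_features)
    return FeatureVector(values, kind="fourier", geometry=binning)


def aperture_cell_mask(width_px: int, cell_size_px: int,
                       aperture_diameter_px: int = None) -> list[tuple[int, int]]:
    """Grid cells whose full square extent lies inside the closed aperture disc.

    The disc is centered at the image center with the given diameter (default:
    the image width, i.e. the inscribed circle).  Cells are returned in
    row-major order.  At the canonical 200-px width this keeps 276/60/9 of the
    400/100/25 cells for 10/20/40-px cells.
    """
    if width_px % cell_size_px != 0:
        raise ValueError(f"width {width_px} not divisible by cell size {cell_size_px}")
    if aperture_diameter_px is None:
        aperture_diameter_px = width_px
    n = width_px // cell_size_px
    c = width_px / 2.0
    r2 = (aperture_diameter_px / 2.0) ** 2
    kept = []
    corners = np.array([(0, 0), (0, 1), (1, 0), (1, 1)], dtype=float)
    for i in range(n):
        for j in range(n):
            pts = (np.array([j, i]) + corners) * cell_size_px
            if np.all(((pts[:, 0] - c) ** 2 + (pts[:, 1] - c) ** 2) <= r2):
                kept.append((i, j))
    return kept


def _hog_cell_histograms(pixels: np.ndarray, spec: HOGSpec) -> np.ndarray:
    """All per-cell histograms on the full grid, shape (grid, grid, n_bins).

    Centered-difference gradients (one-sided at borders), unsigned orientation
    over [0°, 180°), magnitude-weighted votes split bilinearly between the two
    nearest orientation-bin centers (centers at k·180/n_bins, circular over
    180°), per-cell L2 normalization with a small epsilon.
    """
    gy, gx = np.gradient(pixels)
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0

    nb = spec.n_orientation_bins
    binw = 180.0 / nb
    pos = theta / binw
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo %= nb
    hi = (lo + 1) % nb

    g = spec.grid_size
    cs = spec.cell_size_px
    rows = np.arange(pixels.shape[0]) // cs
    cols = np.arange(pixels.shape[1]) // cs
    cell_r, cell_c = np.meshgrid(rows, cols, indexing="ij")

    def accumulate(bins, weights):
        flat = (cell_r * g + cell_c) * nb + bins
        return np.bincount(flat.ravel(), weights=weights.ravel(), minlength=g * g * nb)

    hist = accumulate(lo, mag * (1 - frac)) + accumulate(hi, mag * frac)
    hist = hist.reshape(g, g, nb)
    norm = np.sqrt(np.sum(hist**2, axis=2, keepdims=True) + 1e-12)
    return hist / norm


def hog_features(img: StimulusImage, spec: HOGSpec = None) -> FeatureVector:
    """Aperture-masked HOG descriptor: kept cells' histograms, row-major."""
    if spec is None:
        spec = HOGSpec(width_px=img.width_px)
    if img.width_px != spec.width_px:
        raise ValueError("image width does not match HOG spec")
    if img.width_px < spec.cell_size_px:
        raise ValueError("image smaller than one cell")

    hist = _hog_cell_histograms(img.pixels, spec)
    kept = spec.kept_cells
    values = np.concatenate([hist[r, c] for (r, c) in kept])
    return FeatureVector(values, kind="hog", geometry=spec)


def trial_difference(left: FeatureVector, right: FeatureVector,
                     chosen_side: str, condition: tuple[str, str] = ("", ""),
                     soa_ms: int = 0) -> TrialDifference:
    """Right-minus-left difference; label 1 iff the right image was chosen."""
    if left.kind != right.kind or left.geometry != right.geometry:
        raise ValueError("left/right feature geometries do not match")
    if chosen_side not in ("left", "right"):
        raise ValueError(f"chosen_side must be 'left' or 'right', got {chosen_side!r}")
    diff = FeatureVector(right.values - left.values, kind=left.kind,
                         geometry=left.geometry)
    return TrialDifference(diff, label=int(chosen_side == "right"),
                           condition=condition, soa_ms=soa_ms)


# ---------------------------------------------------------------------------
# bulk helpers / IO
# ---------------------------------------------------------------------------

def feature_matrix(images, extractor, geometry=None) -> np.ndarray:
    """Stack features of many images into an (n_images, n_features) array.

    ``extractor`` is :func:`fourier_features` or :func:`hog_features`.
    """
    return np.vstack([extractor(img, geometry).values for img in images])


def feature_table(images, extractor, geometry=None) -> pd.DataFrame:
    """Per-image feature DataFrame with geometry-encoding column names."""
    X = feature_matrix(images, extractor, geometry)
    if geometry is None:
        geometry = (FourierBinning() if extractor is fourier_features else HOGSpec())
    df = pd.DataFrame(X, columns=geometry.feature_names())
    df.insert(0, "identity", [im.identity for im in images])
    df.insert(1, "expression", [im.expression for im in images])
    return df


def geometry_to_json(geometry, path=None) -> str:
    """Serialize a FourierBinning or HOGSpec descriptor as JSON."""
    if isinstance(geometry, FourierBinning):
        d = {
            "kind": "fourier",
            "n_sf_bands": geometry.n_sf_bands,
            "n_orientation_bands": geometry.n_orientation_bands,
            "width_px": geometry.width_px,
            "sf_band_edges": list(geometry.sf_band_edges),
            "orientation_band_edges": list(geometry.orientation_band_edges),
        }
    elif isinstance(geometry, HOGSpec):
        d = {
            "kind": "hog",
            "cell_size_px": geometry.cell_size_px,
            "n_orientation_bins": geometry.n_orientation_bins,
            "width_px": geometry.width_px,
            "aperture_diameter_px": geometry.aperture_diameter_px,
            "kept_cells": [list(rc) for rc in geometry.kept_cells],
        }
    else:
        raise TypeError(f"unsupported geometry {type(geometry)}")
    text = json.dumps(d, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
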