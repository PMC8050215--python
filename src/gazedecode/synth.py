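"""Synthetic face stimuli, trial tables and choice behaviour with known truth.

The generator emulates the structure of a saccadic two-alternative face-choice
experiment: 4 "expression" classes × many identities rendered as parametric
grayscale composites inside a circular aperture, a counterbalanced trial table
(every ordered expression pair is a condition), and choices produced by a
sparse linear readout of right-minus-left feature differences through a
probit link with lateral bias and lapses.

Faces are built from smooth part primitives (skin oval, eyes, brows, mouth,
teeth band, nasolabial folds) whose parameters have class means and
identity-level jitter, giving each class its own localized oriented-contrast
signature — the statistical structure the downstream decoding needs — without
any photographic content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .features import (
    FourierBinning,
    HOGSpec,
    StimulusImage,
    feature_matrix,
    fourier_features,
    hog_features,
)

__all__ = [
    "ExpressionTemplate",
    "ChoiceModel",
    "TrialDesign",
    "SyntheticExperiment",
    "default_templates",
    "generate_faces",
    "generate_trials",
    "simulate_choices",
    "planted_truth",
    "make_planted_model",
    "calibrate_noise_sd",
    "orthogonalize_to_classes",
    "generate_experiment",
    "write_experiment",
]

EXPRESSIONS = ("happy", "angry", "sad", "neutral")

#: identity-level face geometry (mean, spread); shared across expressions of
#: one identity so the same synthetic person appears in all four classes
_GEOMETRY = {
    "face_width": (0.82, 0.04),
    "face_height": (0.95, 0.03),
    "eye_dx": (0.32, 0.02),
    "eye_y": (-0.25, 0.02),
    "mouth_y": (0.42, 0.03),
    "skin": (0.66, 0.03),
}


@dataclass(frozen=True)
class ExpressionTemplate:
    """Class means and identity-level spreads of the face part parameters.

    Parameters: ``brow_angle`` (deg; negative = inner brow lowered),
    ``eye_aperture`` (vertical eye-opening scale), ``mouth_curvature``
    (positive = corners up), ``mouth_open`` (teeth-band contrast in [0,1]),
    ``fold_strength`` (nasolabial-fold contrast).
    """

    name: str
    means: dict
    spreads: dict

    def __post_init__(self):
        if set(self.means) != set(self.spreads):
            raise ValueError("means and spreads must cover the same parameters")
        if self.means["mouth_open"] < 0 or self.means["mouth_open"] > 1:
            raise ValueError("mouth_open must lie in [0, 1]")


def default_templates() -> list[ExpressionTemplate]:
    """Four distinct expression classes (happy, angry, sad, neutral)."""
    spreads = {
        "brow_angle": 4.0,
        "eye_aperture": 0.08,
        "mouth_curvature": 0.015,
        "mouth_open": 0.06,
        "fold_strength": 0.08,
    }

    def t(name, brow, aperture, curv, open_, fold):
        means = {
            "brow_angle": brow,
            "eye_aperture": aperture,
            "mouth_curvature": curv,
            "mouth_open": open_,
            "fold_strength": fold,
        }
        return ExpressionTemplate(name, means, dict(spreads))

    return [
        t("happy", 5.0, 1.00, 0.080, 0.55, 0.50),
        t("angry", -25.0, 0.80, -0.050, 0.15, 0.30),
        t("sad", 20.0, 0.90, -0.070, 0.00, 0.15),
        t("neutral", 0.0, 1.00, 0.000, 0.00, 0.00),
    ]


# ---------------------------------------------------------------------------
# face rendering
# ---------------------------------------------------------------------------

def _render_face(width: int, p: dict, texture: np.ndarray = None) -> np.ndarray:
    """Render one face from a full parameter dict; deterministic."""
    bg = 0.5
    c = (width - 1) / 2.0
    yy, xx = np.mgrid[0:width, 0:width]
    x = (xx - c) / (width / 2.0)
    y = (yy - c) / (width / 2.0)

    img = np.full((width, width), bg)

    # skin oval (smooth edge)
    e = (x / p["face_width"]) ** 2 + (y / p["face_height"]) ** 2
    face = 1.0 / (1.0 + np.exp(-(1.0 - e) / 0.04))
    img += (p["skin"] - bg) * face

    for sx in (-1.0, 1.0):
        ex = (x - sx * p["eye_dx"]) / 0.13
        ey = (y - p["eye_y"]) / (0.055 * max(p["eye_aperture"], 0.2))
        img -= 0.25 * np.exp(-(ex**2 + ey**2))          # eye white shadow
        px_ = (x - sx * p["eye_dx"]) / 0.035
        py_ = (y - p["eye_y"]) / 0.035
        img -= 0.25 * np.exp(-(px_**2 + py_**2))        # pupil

        # brow: elongated ridge above the eye, mirrored rotation
        a = np.radians(sx * p["brow_angle"])
        bx = x - sx * p["eye_dx"]
        by = y - (p["eye_y"] - 0.14)
        u = np.cos(a) * bx + np.sin(a) * by
        v = -np.sin(a) * bx + np.cos(a) * by
        img -= 0.30 * np.exp(-((u / 0.13) ** 2 + (v / 0.022) ** 2))

        # nasolabial fold: diagonal ridge from nose wing to mouth corner
        fa = np.radians(sx * 55.0)
        fx_ = x - sx * 0.20
        fy_ = y - (p["mouth_y"] - 0.13)
        fu = np.cos(fa) * fx_ + np.sin(fa) * fy_
        fv = -np.sin(fa) * fx_ + np.cos(fa) * fy_
        img -= 0.22 * p["fold_strength"] * np.exp(-((fu / 0.10) ** 2 + (fv / 0.018) ** 2))

    # nose: faint vertical ridge
    img += 0.08 * np.exp(-((x / 0.04) ** 2 + ((y - 0.05) / 0.22) ** 2))

    # mouth: curved dark lip line; curvature>0 pulls corners up (smaller y)
    t = x / 0.28
    span = np.exp(-(t**4))
    center_y = p["mouth_y"] + p["mouth_curvature"] * 4.0 * (t**2 - 0.5)
    img -= 0.30 * span * np.exp(-(((y - center_y) / 0.018) ** 2))
    # teeth: bright high-contrast band just above the lip line when mouth open
    img += 0.45 * p["mouth_open"] * span * np.exp(
        -(((y - center_y + 0.035) / 0.020) ** 2)
    )

    if texture is not None:
        img += texture

    np.clip(img, 0.0, 1.0, out=img)
    inside = (xx - c) ** 2 + (yy - c) ** 2 <= (width / 2.0) ** 2
    img[~inside] = bg
    return img


def generate_faces(templates=None, n_identities: int = 39, seed: int = 0,
                   width: int = 200, identity_jitter: float = 1.0,
                   texture_amplitude: float = 0.10,
                   texture_sigma_px: float = 3.0) -> list[StimulusImage]:
    """Render ``len(templates) × n_identities`` stimuli, deterministic per seed.

    Identity-level deviations — face geometry, per-part parameters and a
    smooth idiosyncratic texture field (Gaussian-filtered noise, emulating
    skin/hair detail that gives real faces their high-dimensional
    identity-specific structure) — are drawn once per identity, shared
    across its four expressions, and scaled by ``identity_jitter``; at 0
    every identity in a class is pixel-identical.
    """
    from scipy.ndimage import gaussian_filter

    if n_identities < 2:
        raise ValueError("need at least 2 identities")
    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(seed)

    identities = []
    for _ in range(n_identities):
        geo = {k: m + identity_jitter * s * rng.standard_normal()
               for k, (m, s) in _GEOMETRY.items()}
        part_z = {k: rng.standard_normal() for k in templates[0].means}
        # the raw field is drawn unconditionally so the random stream (and
        # hence all other identity parameters) is identical across runs that
        # differ only in texture amplitude
        field = rng.standard_normal((width, width))
        tex = None
        if texture_amplitude > 0 and identity_jitter > 0:
            field = gaussian_filter(field, texture_sigma_px)
            field /= max(field.std(), 1e-12)
            tex = identity_jitter * texture_amplitude * field
        identities.append((geo, part_z, tex))

    images = []
    for tpl in templates:
        for ident, (geo, part_z, tex) in enumerate(identities):
            params = dict(geo)
            for k, mean in tpl.means.items():
                params[k] = mean + identity_jitter * tpl.spreads[k] * part_z[k]
            params["mouth_open"] = float(np.clip(params["mouth_open"], 0.0, 1.0))
            params["fold_strength"] = float(np.clip(params["fold_strength"], 0.0, 2.0))
            params["eye_aperture"] = float(np.clip(params["eye_aperture"], 0.2, 2.0))
            images.append(StimulusImage(_render_face(width, params, tex),
                                        identity=f"id{ident:02d}",
                                        expression=tpl.name))
    return images


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Counterbalanced two-face design.

    Every ordered (left, right) expression pair is a condition (16 for four
    classes), so each unordered pair appears equally often on each side.
    Catch trials repeat the design with a nonzero stimulus-onset offset drawn
    from ``soa_levels_ms``.
    """

    n_repeats: int = 56
    catch_repeats: int = 14
    soa_levels_ms: tuple = (34, 50, 67, 84, 100, 117, 134)
    pairs: str = "all"  # "all" | "different" | "same"

    def conditions(self, expressions) -> list[tuple[str, str]]:
        conds = [(a, b) for a in expressions for b in expressions]
        if self.pairs == "different":
            conds = [c for c in conds if c[0] != c[1]]
        elif self.pairs == "same":
            conds = [c for c in conds if c[0] == c[1]]
        return conds


def generate_trials(images, design: TrialDesign = None, seed: int = 0) -> pd.DataFrame:
    """Trial table over the rendered stimuli (no choices yet).

    Columns: trial_id, left_id, right_id, left_class, right_class, soa_ms,
    left_index, right_index (row indices into ``images``).  Identities always
    differ within a trial; main trials have soa_ms = 0.
    """
    if design is None:
        design = TrialDesign()
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[int]] = {}
    for idx, im in enumerate(images):
        by_class.setdefault(im.expression, []).append(idx)
    expressions = [e for e in EXPRESSIONS if e in by_class] or sorted(by_class)
    for e, idxs in by_class.items():
        if len(idxs) < 2:
            raise ValueError(f"need >= 2 identities in class {e!r}")

    rows = []
    for soa_set, repeats in (((0,), design.n_repeats),
                             (design.soa_levels_ms, design.catch_repeats)):
        if repeats <= 0:
            continue
        for (a, b) in design.conditions(expressions):
            for _ in range(repeats):
                while True:
                    li = int(rng.choice(by_class[a]))
                    ri = int(rng.choice(by_class[b]))
                    if images[li].identity != images[ri].identity:
                        break
                soa = int(rng.choice(soa_set)) if len(soa_set) > 1 else soa_set[0]
                rows.append((li, ri, a, b, soa))

    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order],
                      columns=["left_index", "right_index", "left_class",
                               "right_class", "soa_ms"])
    df["left_id"] = [images[i].identity for i in df["left_index"]]
    df["right_id"] = [images[i].identity for i in df["right_index"]]
    df.insert(0, "trial_id", np.arange(len(df)))
    return df[["trial_id", "left_id", "right_id", "left_class", "right_class",
               "soa_ms", "left_index", "right_index"]]


# ---------------------------------------------------------------------------
# choice model
# ---------------------------------------------------------------------------

@dataclass
class ChoiceModel:
    """Sparse linear probit readout of feature differences.

    P(choose right) = (1−lapse)·Φ((w·d − b)/noise_sd) + lapse/2, where d is
    the right-minus-left difference restricted to ``informative_features``
    and b shifts choices toward the left side: ``lateral_bias`` is the
    probability offset toward left at zero signal, i.e. with w·d = 0,
    P(right) = 0.5 − lateral_bias.
    """

    informative_features: np.ndarray
    readout_weights: np.ndarray
    noise_sd: float = 1.0
    lateral_bias: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self):
        self.informative_features = np.atleast_1d(
            np.asarray(self.informative_features, dtype=int))
        self.readout_weights = np.atleast_1d(
            np.asarray(self.readout_weights, dtype=float))
        if self.informative_features.size < 1:
            raise ValueError("need k >= 1 informative features")
        if self.readout_weights.shape != self.informative_features.shape:
            raise ValueError("weights must align with informative features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if not -0.5 < self.lateral_bias < 0.5:
            raise ValueError("lateral_bias must lie in (-0.5, 0.5)")

    @property
    def bias_term(self) -> float:
        if self.lateral_bias == 0.0:
            return 0.0
        return max(self.noise_sd, 1e-12) * norm.ppf(0.5 + self.lateral_bias)


def planted_truth(model: ChoiceModel) -> np.ndarray:
    """Ground-truth informative feature indices, for recovery scoring."""
    return model.informative_features.copy()


def simulate_choices(feature_diffs: np.ndarray, model: ChoiceModel, seed: int = 0):
    """Sample chosen-side labels for each trial difference vector.

    Returns ``(labels, p_right)`` with labels in {0,1} (1 = right chosen).
    ``noise_sd = 0`` is the deterministic limit: label = 1(w·d > b), ties 0.5.
    """
    D = np.asarray(feature_diffs, dtype=float)
    if D.ndim != 2:
        raise ValueError("feature_diffs must be 2-D (trials × features)")
    if model.informative_features.max() >= D.shape[1]:
        raise IndexError("informative feature index out of range")
    s = D[:, model.informative_features] @ model.readout_weights
    if model.noise_sd == 0:
        p = np.where(s > model.bias_term, 1.0,
                     np.where(s < model.bias_term, 0.0, 0.5))
    else:
        p = norm.cdf((s - model.bias_term) / model.noise_sd)
    p = (1.0 - model.lapse_rate) * p + model.lapse_rate / 2.0
    rng = np.random.default_rng(seed)
    labels = (rng.random(len(p)) < p).astype(int)
    return labels, p


def calibrate_noise_sd(feature_diffs, model_or_weights, informative=None,
                       target_bayes: float = 0.70) -> float:
    """Noise level at which the ideal observer hits a target accuracy.

    The ideal observer predicts sign(w·d); its accuracy on the realized trial
    differences is mean Φ(|w·d|/σ), monotone decreasing in σ, so σ is found
    by bisection.  ``target_bayes`` must lie in (0.5, max attainable).
    """
    if isinstance(model_or_weights, ChoiceModel):
        w = model_or_weights.readout_weights
        informative = model_or_weights.informative_features
    else:
        w = np.asarray(model_or_weights, dtype=float)
        if informative is None:
            raise ValueError("informative indices required with raw weights")
    s = np.abs(np.asarray(feature_diffs)[:, np.asarray(informative, dtype=int)] @ w)
    if not 0.5 < target_bayes < 1.0:
        raise ValueError("target accuracy must lie in (0.5, 1)")

    def acc(sigma):
        return float(np.mean(norm.cdf(s / sigma)))

    lo, hi = 1e-9, 1.0
    while acc(hi) > target_bayes:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if acc(mid) > target_bayes:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def orthogonalize_to_classes(weights, informative, class_means) -> np.ndarray:
    """Project readout weights orthogonal to the class-mean structure.

    ``class_means`` is (n_classes × n_features) over single-image features.
    After projection, E[w·(right − left) | class pair] = 0 for every pair, so
    the simulated choices carry no emotion-content signal — only
    identity-level feature variation drives them.
    """
    w = np.asarray(weights, dtype=float).copy()
    inf = np.asarray(informative, dtype=int)
    B = np.asarray(class_means)[:, inf]
    B = B - B.mean(axis=0, keepdims=True)
    # orthonormal basis of the class-contrast span restricted to informative coords
    q, r = np.linalg.qr(B.T)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    w_proj = w - q @ (q.T @ w)
    n = np.linalg.norm(w_proj)
    if n < 1e-12:
        raise ValueError("weights lie entirely in the class-contrast span")
    return w_proj / n * np.linalg.norm(w)


def make_planted_model(n_features: int, k: int = 10, seed: int = 0,
                       noise_sd: float = 1.0, lateral_bias: float = 0.0,
                       lapse_rate: float = 0.0, feature_variances=None,
                       groups=None, weight_mode: str = "equal",
                       eligible_mask=None) -> ChoiceModel:
    """Random sparse readout over k distinct feature indices.

    ``weight_mode="equal"`` (default) gives every informative feature the
    same weight magnitude with a random sign, so each of the k features
    genuinely contributes; ``"gaussian"`` draws unit-norm Gaussian weights.

    With ``feature_variances`` given (per-feature variance of the trial
    differences or image features), the k indices are drawn from the upper
    half of the variance distribution, so the planted readout reads stimulus
    content that actually varies — a readout of near-constant features would
    be unidentifiable by construction.  ``groups`` (per-feature group ids,
    e.g. the HOG cell of each feature) restricts the draw to one feature per
    group, spreading the readout across the stimulus.  ``eligible_mask``
    further restricts the candidate pool (e.g. to features whose variance is
    dominated by identity-specific rather than expression-category content).
    """
    if k < 1:
        raise ValueError("need k >= 1")
    rng = np.random.default_rng(seed)
    eligible = np.ones(n_features, dtype=bool)
    if eligible_mask is not None:
        eligible &= np.asarray(eligible_mask, dtype=bool)
    if feature_variances is not None:
        v = np.asarray(feature_variances, dtype=float)
        if len(v) != n_features:
            raise ValueError("feature_variances length mismatch")
        if eligible.any():
            eligible &= v >= np.median(v[eligible])
    pool = np.flatnonzero(eligible)
    if groups is None:
        if len(pool) < k:
            raise ValueError("not enough eligible features to plant in")
        idx = np.sort(rng.choice(pool, size=k, replace=False))
    else:
        groups = np.asarray(groups)
        chosen, used = [], set()
        for f in rng.permutation(pool):
            g = groups[f]
            if g not in used:
                chosen.append(int(f))
                used.add(g)
            if len(chosen) == k:
                break
        if len(chosen) < k:
            raise ValueError("not enough distinct groups to plant in")
        idx = np.sort(chosen)
    if weight_mode == "equal":
        w = rng.choice([-1.0, 1.0], size=k) / np.sqrt(k)
    elif weight_mode == "balanced":
        # equal variance contribution: weight ∝ 1/sd of the feature, so each
        # informative feature carries the same share of the decision variable
        if feature_variances is None:
            raise ValueError("balanced weights require feature_variances")
        sd = np.sqrt(np.asarray(feature_variances, dtype=float)[idx])
        w = rng.choice([-1.0, 1.0], size=k) / np.maximum(sd, 1e-12)
        w /= np.linalg.norm(w)
    elif weight_mode == "gaussian":
        w = rng.standard_normal(k)
        w /= np.linalg.norm(w)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return ChoiceModel(idx, w, noise_sd=noise_sd, lateral_bias=lateral_bias,
                       lapse_rate=lapse_rate)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """A complete simulated session with ground truth attached."""

    images: list
    trials: pd.DataFrame            # includes chosen_side
    truth: ChoiceModel
    image_features: np.ndarray      # (n_images × n_features)
    diffs: np.ndarray               # (n_trials × n_features), right − left
    labels: np.ndarray              # 1 = right chosen
    p_right: np.ndarray
    geometry: object
    seed: int

    @property
    def class_means(self) -> np.ndarray:
        classes = sorted({im.expression for im in self.images})
        return np.vstack([
            self.image_features[[i for i, im in enumerate(self.images)
                                 if im.expression == c]].mean(axis=0)
            for c in classes
        ])


def experiment_subseeds(seed: int):
    """The (faces, trials, choices) sub-seeds a given experiment seed expands
    into; exposed so twin stimulus sets (e.g. a zero-texture control render)
    can be generated against the same identity parameters."""
    ss = np.random.SeedSequence(seed)
    return tuple(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))


def _extractor_for(feature_space: str):
    if feature_space == "fourier":
        return fourier_features, FourierBinning()
    if feature_space.startswith("hog"):
        cell = int(feature_space[3:] or 10)
        return hog_features, HOGSpec(cell_size_px=cell)
    raise ValueError(f"unknown feature space {feature_space!r}")


def generate_experiment(n_identities: int = 39, design: TrialDesign = None,
                        model: ChoiceModel = None, feature_space: str = "fourier",
                        seed: int = 0, templates=None, identity_jitter: float = 1.0,
                        target_bayes: float = None, width: int = 200,
                        emotion_orthogonal: bool = False) -> SyntheticExperiment:
    """Generate images, trials, features and choices in one deterministic call.

    ``model=None`` plants a zero-signal observer (pure noise choices).  With
    ``target_bayes`` set, the model's noise_sd is re-calibrated so the ideal
    observer's accuracy on the realized trial differences equals the target.
    ``emotion_orthogonal=True`` projects the readout weights orthogonal to
    the class-mean feature structure before simulating.
    """
    s_faces, s_trials, s_choice = experiment_subseeds(seed)

    extractor, geometry = _extractor_for(feature_space)
    images = generate_faces(templates, n_identities, seed=s_faces, width=width,
                            identity_jitter=identity_jitter)
    trials = generate_trials(images, design, seed=s_trials)
    X = feature_matrix(images, extractor, geometry)
    D = X[trials["right_index"].to_numpy()] - X[trials["left_index"].to_numpy()]

    if model is None:
        # zero-signal observer: one dummy feature with zero weight
        model = ChoiceModel(np.array([0]), np.array([0.0]), noise_sd=1.0)
    if emotion_orthogonal:
        classes = sorted({im.expression for im in images})
        means = np.vstack([X[[i for i, im in enumerate(images)
                              if im.expression == c]].mean(axis=0) for c in classes])
        model = ChoiceModel(model.informative_features,
                            orthogonalize_to_classes(model.readout_weights,
                                                     model.informative_features, means),
                            noise_sd=model.noise_sd,
                            lateral_bias=model.lateral_bias,
                            lapse_rate=model.lapse_rate)
    if target_bayes is not None:
        sd = calibrate_noise_sd(D, model, target_bayes=target_bayes)
        model = ChoiceModel(model.informative_features, model.readout_weights,
                            noise_sd=sd, lateral_bias=model.lateral_bias,
                            lapse_rate=model.lapse_rate)

    labels, p = simulate_choices(D, model, seed=s_choice)
    trials = trials.copy()
    trials["chosen_side"] = np.where(labels == 1, "right", "left")
    return SyntheticExperiment(images, trials, model, X, D, labels, p,
                               geometry, seed)


def write_experiment(exp: SyntheticExperiment, outdir) -> None:
    """Write stimuli as PNG, the trial table as CSV and the truth as JSON."""
    import json
    from pathlib import Path

    from PIL import Image

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    for im in exp.images:
        arr = (np.clip(im.pixels, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"{im.identity}_{im.expression}.png")
    cols = ["trial_id", "left_id", "right_id", "left_class", "right_class",
            "soa_ms", "chosen_side"]
    exp.trials[cols].to_csv(out / "trials.csv", index=False)
    truth = {
        "informative_features": exp.truth.informative_features.tolist(),
        "readout_weights": exp.truth.readout_weights.tolist(),
        "noise_sd": exp.truth.noise_sd,
        "lateral_bias": exp.truth.lateral_bias,
        "lapse_rate": exp.truth.lapse_rate,
        "seed": exp.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
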