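"""Seeded synthetic cohorts: face-like region images and direct feature tables.

No public image cohort exists for the benign-nodule vs lung-cancer facial
analysis, so this module generates the study conditions the pipeline
assumes, in two forms:

* :func:`generate_cohort` draws region-structured face-like images whose
  per-region colors follow class-conditional Gaussians around a mid-tone
  base skin color, with optional class-dependent color shifts (e.g. a
  saturation shift in the forehead, a hue shift in the lip) and
  class-dependent texture granularity (Gaussian-smoothed luminance noise
  whose kernel width controls GLCM contrast/IDM).  Masks are ground truth
  by construction: a fixed geometric template of rectangles and ellipses at
  canonical face positions.

* :func:`generate_feature_table` samples the 124-feature schema directly
  from class-conditional multivariate Gaussians with block correlation
  structure.  The default blocks emulate the correlation pattern reported
  for real cohorts: extremely strong positive correlation among
  intra-channel color features across regions, and strong negative
  correlation between the GLCM-idm and GLCM-con series.  Features are on a
  standardized scale (unit variance), so planted class effects are
  per-SD log-odds shifts.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv

from .face_features import FEATURE_NAMES, REGION_NAMES, RegionSet, regions_from_labelmap

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "default_corr_blocks",
    "build_correlation",
    "template_regions",
    "generate_cohort",
    "generate_feature_table",
    "generate_demographics",
    "write_cohort",
    "read_cohort",
]

BASE_SKIN_RGB = (200.0, 160.0, 140.0)
BASE_LIP_RGB = (170.0, 90.0, 95.0)
SUBJECT_JITTER_SD = 8.0

# Class-conditional demographics matching the reported development cohort:
# benign-nodule patients are younger (median ~46) and less often male than
# lung-cancer patients (median age ~66, ~55% male).
AGE_PARAMS = {0: (46.0, 13.0), 1: (64.0, 10.0)}
MALE_PROB = {0: 0.431, 1: 0.553}


class SizingError(ValueError):
    """Image too small to place the 9 disjoint template regions."""


def default_corr_blocks() -> list[dict]:
    """Correlation blocks emulating the real-cohort feature structure.

    Intra-channel color features (the same channel across the 9 regions)
    correlate strongly positively; the four GLCM-idm features correlate
    positively with each other, as do the four GLCM-con features, while
    idm/con pairs correlate strongly negatively.
    """
    blocks: list[dict] = []
    for ch in ("R", "G", "B", "H", "S", "V", "L", "a", "b", "Y", "Cr", "Cb"):
        feats = [f"color-{ch}-{i}" for i in range(8)] + [f"lipcolor-{ch}"]
        blocks.append({"features": feats, "r": 0.85})
    idm = [f"GLCM-idm_{k}" for k in range(4)]
    con = [f"GLCM-con_{k}" for k in range(4)]
    blocks.append({"features": idm, "r": 0.8})
    blocks.append({"features": con, "r": 0.8})
    blocks.append({"features": idm, "features_b": con, "r": -0.75})
    return blocks


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions.

    ``color_effects`` maps region name -> channel -> additive mean shift
    applied to class-1 subjects (H/S/V shifts are on the 0-1 fractional
    scale, R/G/B shifts on 0-255).  ``texture_effect`` maps class -> the
    Gaussian smoothing sigma of the luminance noise field (larger sigma =
    coarser, smoother texture = lower GLCM contrast, higher IDM).
    ``effect_sizes`` (table generation) maps feature -> standardized
    class-1 mean shift, i.e. the planted per-SD log-odds.
    """

    n_per_class: int = 250
    image_size: int = 128
    seed: int = 0
    color_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"forehead": {"S": 0.04}, "lip": {"H": 0.01}}
    )
    texture_effect: dict[int, float] = field(default_factory=lambda: {0: 1.2, 1: 2.0})
    noise_amplitude: float = 10.0
    jitter_sd: float = SUBJECT_JITTER_SD
    corr_structure: list[dict] | None = field(default_factory=default_corr_blocks)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    with_demographics: bool = False

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if not (0 <= self.missing_rate < 0.5 and 0 <= self.outlier_rate < 0.5):
            raise ValueError("missing_rate and outlier_rate must lie in [0, 0.5)")
        unknown = set(self.color_effects) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"color_effects for unknown regions: {sorted(unknown)}")
        unknown_feats = set(self.effect_sizes) - set(FEATURE_NAMES)
        if unknown_feats:
            raise ValueError(f"effect_sizes for unknown features: {sorted(unknown_feats)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["texture_effect"] = {str(k): v for k, v in d["texture_effect"].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        if "texture_effect" in d:
            d["texture_effect"] = {int(k): v for k, v in d["texture_effect"].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    images: list[np.ndarray]
    masks: list[RegionSet]
    labels: np.ndarray
    truth: SyntheticConfig

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.masks) == len(self.labels)):
            raise ValueError("images, masks and labels must have equal length")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("labels must contain both classes")


# ---------------------------------------------------------------------------
# Image cohort
# ---------------------------------------------------------------------------

# Template region geometry as fractions of the image side:
# (kind, x0/cx, x1/rx, y0/cy, y1/ry)
_TEMPLATE = {
    "forehead": ("rect", 0.25, 0.75, 0.08, 0.20),
    "glabella": ("rect", 0.42, 0.58, 0.24, 0.32),
    "nasal_tip": ("ellipse", 0.50, 0.07, 0.48, 0.05),
    "mandible": ("rect", 0.38, 0.62, 0.88, 0.96),
    "left_zygomatic": ("rect", 0.12, 0.30, 0.36, 0.46),
    "right_zygomatic": ("rect", 0.70, 0.88, 0.36, 0.46),
    "left_cheek": ("rect", 0.14, 0.34, 0.52, 0.70),
    "right_cheek": ("rect", 0.66, 0.86, 0.52, 0.70),
    "lip": ("ellipse", 0.50, 0.16, 0.78, 0.05),
}


def template_regions(image_size: int) -> RegionSet:
    """The fixed 9-region layout scaled to a square image."""
    if image_size < 32:
        raise SizingError("image_size must be >= 32 to place 9 disjoint regions")
    s = image_size
    masks: dict[str, np.ndarray] = {}
    yy, xx = np.indices((s, s))
    for name, (kind, a, b, c, d) in _TEMPLATE.items():
        if kind == "rect":
            masks[name] = (
                (xx >= round(a * s)) & (xx < round(b * s)) & (yy >= round(c * s)) & (yy < round(d * s))
            )
        else:  # ellipse: (cx, rx, cy, ry)
            masks[name] = ((xx - a * s) / (b * s)) ** 2 + ((yy - c * s) / (d * s)) ** 2 <= 1.0
    return RegionSet(masks)


def _shift_color(rgb: np.ndarray, shifts: dict[str, float]) -> np.ndarray:
    """Apply per-channel shifts to one RGB color (H/S/V fractional, RGB 0-255)."""
    out = rgb.copy()
    rgb_shift = np.array([shifts.get(c, 0.0) for c in "RGB"])
    out = out + rgb_shift
    if any(c in shifts for c in "HSV"):
        hsv = rgb2hsv(np.clip(out, 0, 255)[None, None, :] / 255.0)[0, 0]
        hsv[0] = (hsv[0] + shifts.get("H", 0.0)) % 1.0
        hsv[1] = np.clip(hsv[1] + shifts.get("S", 0.0), 0.0, 1.0)
        hsv[2] = np.clip(hsv[2] + shifts.get("V", 0.0), 0.0, 1.0)
        out = hsv2rgb(hsv[None, None, :])[0, 0] * 255.0
    return out


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw the image cohort: class 0 subjects first, then class 1."""
    rng = np.random.default_rng(config.seed)
    regions = template_regions(config.image_size)
    s = config.image_size
    skin = np.asarray(BASE_SKIN_RGB)
    lip = np.asarray(BASE_LIP_RGB)

    images: list[np.ndarray] = []
    labels = np.repeat([0, 1], config.n_per_class)
    for cls in (0, 1):
        sigma = float(config.texture_effect.get(cls, 1.0))
        for _ in range(config.n_per_class):
            jitter = rng.normal(0.0, config.jitter_sd, size=3)
            img = np.empty((s, s, 3), dtype=float)
            img[:] = skin + jitter
            for name in REGION_NAMES:
                base = lip + jitter if name == "lip" else skin + jitter
                shifts = config.color_effects.get(name, {}) if cls == 1 else {}
                img[regions.masks[name]] = _shift_color(base, shifts)
            noise = rng.normal(0.0, config.noise_amplitude, size=(s, s))
            if sigma > 0:
                noise = gaussian_filter(noise, sigma)
            img += noise[:, :, None]
            images.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
    return SyntheticCohort(images, [regions] * len(images), labels, config)


# ---------------------------------------------------------------------------
# Direct feature tables
# ---------------------------------------------------------------------------


def build_correlation(blocks: list[dict] | None) -> np.ndarray:
    """Assemble the 124x124 correlation matrix from block specs.

    Each block sets ``r`` on all pairs within ``features`` (or, with
    ``features_b``, on all cross pairs between the two lists).  Raises if
    the result is not positive semi-definite.
    """
    p = len(FEATURE_NAMES)
    idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
    corr = np.eye(p)
    for block in blocks or []:
        feats = [idx[f] for f in block["features"]]
        r = float(block["r"])
        if "features_b" in block:
            feats_b = [idx[f] for f in block["features_b"]]
            for i in feats:
                for j in feats_b:
                    if i != j:
                        corr[i, j] = corr[j, i] = r
        else:
            for a, i in enumerate(feats):
                for j in feats[a + 1:]:
                    corr[i, j] = corr[j, i] = r
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("corr_structure is not positive semi-definite")
    return corr


def generate_feature_table(config: SyntheticConfig) -> pd.DataFrame:
    """Sample the 124-column feature table plus a binary ``label`` column.

    Features are standardized (unit variance) class-conditional Gaussians;
    class-1 means are shifted by ``effect_sizes`` so a planted value of 1.0
    corresponds to a per-SD log-odds of 1.0 under equal class priors.
    Missing cells and 8-SD outliers are injected at the configured rates.
    """
    rng = np.random.default_rng(config.seed)
    p = len(FEATURE_NAMES)
    n = config.n_per_class
    corr = build_correlation(config.corr_structure)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    z = rng.standard_normal((2 * n, p)) @ chol.T
    shift = np.array([config.effect_sizes.get(f, 0.0) for f in FEATURE_NAMES])
    labels = np.repeat([0, 1], n)
    z[labels == 1] += shift

    table = pd.DataFrame(z, columns=list(FEATURE_NAMES))

    if config.outlier_rate > 0:
        cells = rng.random((2 * n, p)) < config.outlier_rate
        col_mean = z.mean(axis=0)
        col_sd = z.std(axis=0, ddof=1)
        signs = rng.choice([-1.0, 1.0], size=(2 * n, p))
        out_vals = col_mean + signs * 8.0 * col_sd
        vals = table.to_numpy()
        vals[cells] = out_vals[cells]
        table = pd.DataFrame(vals, columns=list(FEATURE_NAMES))
    if config.missing_rate > 0:
        holes = rng.random((2 * n, p)) < config.missing_rate
        vals = table.to_numpy()
        vals[holes] = np.nan
        table = pd.DataFrame(vals, columns=list(FEATURE_NAMES))

    table["label"] = labels
    if config.with_demographics:
        demo = generate_demographics(labels, rng)
        table = pd.concat([table, demo], axis=1)
    return table


def generate_demographics(labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Age/sex columns with class-dependent distributions (for matching)."""
    labels = np.asarray(labels)
    age = np.empty(len(labels))
    sex = np.empty(len(labels), dtype=int)
    for cls in (0, 1):
        m = labels == cls
        mu, sd = AGE_PARAMS[cls]
        age[m] = np.clip(rng.normal(mu, sd, m.sum()), 25, 90)
        sex[m] = rng.random(m.sum()) < MALE_PROB[cls]
    return pd.DataFrame({"age": np.round(age, 1), "sex": sex})


# ---------------------------------------------------------------------------
# On-disk dialect
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """PNG images, label-map PNG masks (region index + 1), labels.csv, truth.json."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for i, (img, reg) in enumerate(zip(cohort.images, cohort.masks)):
        Image.fromarray(img).save(outdir / "images" / f"subject_{i:04d}.png")
        Image.fromarray(reg.to_labelmap()).save(outdir / "masks" / f"subject_{i:04d}.png")
    pd.DataFrame(
        {"subject": [f"subject_{i:04d}" for i in range(len(cohort.labels))], "label": cohort.labels}
    ).to_csv(outdir / "labels.csv", index=False)
    (outdir / "truth.json").write_text(cohort.truth.to_json())
    return outdir


def read_cohort(indir) -> SyntheticCohort:
    indir = Path(indir)
    labels_df = pd.read_csv(indir / "labels.csv")
    images, masks = [], []
    for subject in labels_df["subject"]:
        images.append(np.asarray(Image.open(indir / "images" / f"{subject}.png").convert("RGB")))
        masks.append(regions_from_labelmap(np.asarray(Image.open(indir / "masks" / f"{subject}.png"))))
    truth = SyntheticConfig.from_json((indir / "truth.json").read_text())
    return SyntheticCohort(images, masks, labels_df["label"].to_numpy(), truth)
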