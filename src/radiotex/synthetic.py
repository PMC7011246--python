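"""Synthetic two-group tumor cohorts with the statistical structure the
analysis assumes.

Each subject's tumor is a filled ellipse (random semi-axes and orientation)
cut out of a Gaussian random field: white noise smoothed by an isotropic
Gaussian kernel whose width — the correlation length — sets the texture's
spatial smoothness without changing its mean intensity.  The two study arms
differ only in texture parameters, mirroring a study design in which texture,
not tumor size, separates the groups.  Survival is linked linearly to each
subject's realized correlation length (the generator parameter, not an
extracted feature, so feature-survival recovery is a genuine task), and
histology markers are generated from designated extracted features through a
jointly Gaussian latent link whose population Pearson correlation equals the
requested target.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning: one child stream per subject plus one per histology marker, so the
cohort is bit-reproducible and individual subjects are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from .errors import ConfigurationError
from .features import FeatureConfig, FeatureExtractor
from .io_preprocess import RoiImage


@dataclass
class TextureParams:
    """Gaussian-random-field texture of one study arm."""

    correlation_length: float  # px; kernel sigma of the smoothing filter
    noise_sd: float = 0.15  # intensity units; marginal SD of the field
    mean_level: float = 0.5  # intensity units


@dataclass
class SurvivalLink:
    """survival = baseline + slope * realized correlation length + noise, floored at 1 d."""

    baseline_days: float = 30.0
    slope: float = 4.2  # days per px of correlation length
    noise_sd_days: float = 19.0


@dataclass
class HistologyLink:
    """A marker correlated with a designated extracted feature.

    marker = loc + noise_sd * (rho * z + sqrt(1 - rho^2) * eps), with z the
    standardized designated feature across the cohort and eps iid standard
    normal, so the population Pearson correlation with the feature is rho.
    """

    marker_name: str
    feature: str
    target_correlation: float
    noise_sd: float = 10.0  # marker scale
    loc: float = 30.0


def default_histology_links() -> list[HistologyLink]:
    """The study-like marker set: fibrosis %, CK19 %, Ki67 cells/field."""
    return [
        HistologyLink("fibrosis_pct", "hog.fos.entropy", 0.84, noise_sd=8.0, loc=25.0),
        HistologyLink("ck19_pct", "hog.fos.entropy", -0.97, noise_sd=10.0, loc=30.0),
        HistologyLink("ki67_per_field", "wav_v.fos.mean", 0.81, noise_sd=12.0, loc=40.0),
    ]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort (defaults emulate the study:
    8 + 8 subjects, texture-separated arms, survival ~55 vs ~34 days with
    ~19-day within-group spread)."""

    n_per_group: int = 8
    image_size: int = 64
    tumor_axes_range: tuple[float, float] = (8.0, 14.0)  # semi-axes, px
    texture_params_control: TextureParams = field(
        default_factory=lambda: TextureParams(correlation_length=1.0)
    )
    texture_params_treated: TextureParams = field(
        default_factory=lambda: TextureParams(correlation_length=6.0)
    )
    survival_link: SurvivalLink = field(default_factory=SurvivalLink)
    histology_link: list[HistologyLink] = field(default_factory=default_histology_links)
    correlation_length_jitter_sd: float = 1.0  # px; per-subject texture variation
    censoring_fraction: float = 0.0  # events observed for everyone by default
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError(f"n_per_group must be >= 2, got {self.n_per_group}")
        lo, hi = self.tumor_axes_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"tumor_axes_range must satisfy 0 < lo <= hi, got {lo, hi}")
        if 2 * hi >= self.image_size:
            raise ConfigurationError(
                f"tumor_axes_range: max semi-axis {hi} does not fit an "
                f"{self.image_size}-px canvas"
            )
        for link in self.histology_link:
            if abs(link.target_correlation) > 1:
                raise ConfigurationError(
                    f"histology_link[{link.marker_name}]: |target_correlation| must be <= 1"
                )
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ConfigurationError("censoring_fraction must be in [0, 1)")


@dataclass
class Subject:
    subject_id: str
    roi: RoiImage
    group_label: str  # "control" | "treated"
    survival_days: float
    event: bool
    histology: dict[str, float]
    correlation_length: float  # realized generator parameter (ground truth)


@dataclass
class CohortDataset:
    subjects: list[Subject]
    config: SyntheticCohortConfig

    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group_label,
                "survival_days": s.survival_days,
                "event": s.event,
            }
            row.update(s.histology)
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")

    def rois(self) -> list[RoiImage]:
        return [s.roi for s in self.subjects]

    def labels(self) -> pd.Series:
        return self.metadata()["group"]


def _random_field(rng: np.random.Generator, size: int, params: TextureParams,
                  corr_len: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=(size, size))
    smooth = gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd  # restore unit marginal SD after smoothing
    return params.mean_level + params.noise_sd * smooth


def _ellipse_mask(rng: np.random.Generator, size: int,
                  axes_range: tuple[float, float]) -> np.ndarray:
    a = rng.uniform(*axes_range)
    b = rng.uniform(*axes_range)
    theta = rng.uniform(0.0, np.pi)
    rr, cc = ellipse(size / 2.0, size / 2.0, a, b, shape=(size, size), rotation=theta)
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_cohort(config: SyntheticCohortConfig | None = None) -> CohortDataset:
    """Generate a two-arm cohort per the configured study conditions."""
    config = config or SyntheticCohortConfig()
    config.validate()
    n = config.n_per_group
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(2 * n)
    marker_seeds = root.spawn(len(config.histology_link))

    subjects: list[Subject] = []
    arms = [("control", config.texture_params_control),
            ("treated", config.texture_params_treated)]
    idx = 0
    for label, params in arms:
        for j in range(n):
            rng = np.random.default_rng(subject_seeds[idx])
            idx += 1
            cl = max(0.3, params.correlation_length
                     + rng.normal(0.0, config.correlation_length_jitter_sd))
            pixels = _random_field(rng, config.image_size, params, cl)
            mask = _ellipse_mask(rng, config.image_size, config.tumor_axes_range)
            sid = f"{label[:3]}{j + 1:02d}"
            roi = RoiImage(pixels=pixels, mask=mask, subject_id=sid)
            link = config.survival_link
            surv = max(1.0, link.baseline_days + link.slope * cl
                       + rng.normal(0.0, link.noise_sd_days))
            event = bool(rng.uniform() >= config.censoring_fraction)
            subjects.append(Subject(sid, roi, label, float(surv), event, {}, float(cl)))

    # histology markers from designated extracted features (latent Gaussian link)
    if config.histology_link:
        extractor = FeatureExtractor(FeatureConfig())
        needed = sorted({link.feature for link in config.histology_link})
        feats = {s.subject_id: extractor.extract_named(s.roi, needed) for s in subjects}
        for link, seed in zip(config.histology_link, marker_seeds):
            rng = np.random.default_rng(seed)
            f = np.array([feats[s.subject_id][link.feature] for s in subjects])
            sd = f.std()
            z = (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)
            rho = link.target_correlation
            eps = rng.normal(0.0, 1.0, size=len(subjects))
            marker = link.loc + link.noise_sd * (rho * z + np.sqrt(1.0 - rho**2) * eps)
            for s, m in zip(subjects, marker):
                s.histology[link.marker_name] = float(m)

    return CohortDataset(subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# disk round trip (16-bit PNG image + mask pairs and a metadata CSV)

def save_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs and metadata.csv; returns the directory."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for s in dataset.subjects:
        px = s.roi.pixels
        lo, hi = px.min(), px.max()
        scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
        iio.imwrite(out_dir / "images" / f"{s.subject_id}.png",
                    (scaled * 65535).astype(np.uint16))
        iio.imwrite(out_dir / "masks" / f"{s.subject_id}.png",
                    (s.roi.mask * 255).astype(np.uint8))
    meta = dataset.metadata()
    meta.to_csv(out_dir / "metadata.csv")
    return out_dir


def load_cohort_dir(cohort_dir: str | Path):
    """Load (rois, metadata) written by :func:`save_cohort`."""
    from .io_preprocess import read_roi

    cohort_dir = Path(cohort_dir)
    meta = pd.read_csv(cohort_dir / "metadata.csv", index_col="subject_id")
    rois = [
        read_roi(cohort_dir / "images" / f"{sid}.png",
                 cohort_dir / "masks" / f"{sid}.png", subject_id=str(sid))
        for sid in meta.index
    ]
    return rois, meta


# ---------------------------------------------------------------------------
# tiny hand-checkable fixtures shared across test suites

def generate_worked_fixtures() -> dict[str, dict]:
    """Small labelled arrays with hand-computed expected values."""
    return {
        "glrm_toy": {
            "array": np.array([[1, 1, 2], [2, 2, 2]], dtype=np.int64),
            "n_levels": 2,
            "expected": {  # runs at 0 degrees: (g=1,l=2), (g=2,l=1), (g=2,l=3)
                "sre": (1 / 4 + 1 + 1 / 9) / 3,
                "lre": 14 / 3,
                "rp": 0.5,
                "gln": 5 / 3,
                "rln": 1.0,
                "lgre": 0.5,
            },
        },
        "haar_toy": {
            "array": np.array([[1.0, 3.0], [5.0, 7.0]]),
            "expected": {"approximate": 8.0, "horizontal": -4.0, "vertical": -2.0,
                         "diagonal": 0.0, "energy": 84.0},
        },
        "glcm_toy": {
            "array": np.array([[1, 1], [2, 2]], dtype=np.int64),
            "n_levels": 2,
            "expected": {
                "deg0": {"contrast": 0.0, "energy": 0.5, "homogeneity": 1.0,
                         "entropy": 1.0, "correlation": 1.0, "dissimilarity": 0.0},
                "deg90": {"contrast": 1.0, "correlation": -1.0},
            },
        },
    }
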