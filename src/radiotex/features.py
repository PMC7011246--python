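"""The canonical 152-feature texture vector for a 2D tumor ROI.

Seven feature families — first-order statistics (FoS), gray-level co-occurrence
matrix (GLCM), gray-level run-length matrix (GLRM), local binary patterns
(LBP), fractal analysis, histogram of oriented gradients (HoG), and shape —
are combined with two filters (Sobel gradient and single-level Haar wavelet):

=========  =============================================  =====
source     families                                       count
=========  =============================================  =====
base       fos 4, glcm 6, glrm 11, lbp 10, fractal 2,
           shape 6                                           39
grad       fos 4, glcm 6, glrm 11                            21
wav_a..d   power 1, fos 4, glcm 6, glrm 11  (x 4 bands)      88
hog        fos 4                                              4
=========  =============================================  =====

for a total of 152 named features, ``<source>.<family>.<feature>``.  The
inventory (names and order) is frozen: every extraction returns exactly these
names in this order.

Conventions fixed here: matrix features use distance-1 offsets at 0/45/90/135
degrees and are averaged over directions; co-occurrence matrices are
symmetrized and normalized to sum 1; only pixel pairs (and runs) lying wholly
inside the mask count, and a masked-out pixel breaks a run; all entropies are
base 2 with 0*log0 := 0; matrix features are computed on min-max-normalized,
equal-width-quantized values, which makes them invariant to affine intensity
rescaling of the raw image (base FoS, computed on the intensities as given,
is deliberately not invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, EmptyMaskError
from .filters import WaveletBands, eroded_mask, gradient_image, haar_dwt, hog_histogram
from .io_preprocess import QuantizedImage, RoiImage, normalize_masked, normalize_roi

# ---------------------------------------------------------------------------
# canonical inventory

FOS_NAMES = ("mean", "variance", "skewness", "entropy")
GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity", "entropy", "dissimilarity")
GLRM_NAMES = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")
LBP_NAMES = tuple(f"u{k}" for k in range(9)) + ("nonuniform",)
FRACTAL_NAMES = ("fd", "lacunarity")
SHAPE_NAMES = ("area", "perimeter", "circularity", "eccentricity", "solidity", "extent")
POWER_NAMES = ("mean_square",)

WAVELET_SOURCES = ("wav_a", "wav_h", "wav_v", "wav_d")


def _build_inventory() -> tuple[str, ...]:
    names: list[str] = []

    def add(source: str, family: str, feats: tuple[str, ...]) -> None:
        names.extend(f"{source}.{family}.{f}" for f in feats)

    add("base", "fos", FOS_NAMES)
    add("base", "glcm", GLCM_NAMES)
    add("base", "glrm", GLRM_NAMES)
    add("base", "lbp", LBP_NAMES)
    add("base", "fractal", FRACTAL_NAMES)
    add("base", "shape", SHAPE_NAMES)
    add("grad", "fos", FOS_NAMES)
    add("grad", "glcm", GLCM_NAMES)
    add("grad", "glrm", GLRM_NAMES)
    for band in WAVELET_SOURCES:
        add(band, "power", POWER_NAMES)
        add(band, "fos", FOS_NAMES)
        add(band, "glcm", GLCM_NAMES)
        add(band, "glrm", GLRM_NAMES)
    add("hog", "fos", FOS_NAMES)
    return tuple(names)


#: the frozen 152-name feature inventory, in canonical order
FEATURE_NAMES: tuple[str, ...] = _build_inventory()
assert len(FEATURE_NAMES) == 152

#: feature family of each name, for family-level bookkeeping downstream
def family_of(name: str) -> str:
    return name.split(".")[1]


@dataclass
class FeatureConfig:
    """Knobs of the extractor; defaults are the analysis defaults."""

    n_levels: int = 32
    fos_bins: int = 32
    lacunarity_box: int = 4


# ---------------------------------------------------------------------------
# first-order statistics

def fos(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """Mean, population variance, Fisher skewness and histogram entropy (bits).

    Entropy uses an equal-width histogram of ``n_bins`` bins spanning the
    observed min-max; a constant input has entropy 0 (single occupied bin).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise DegenerateInputError(f"fos needs >= 2 values, got {values.size}")
    m = float(values.mean())
    dev = values - m
    m2 = float(np.mean(dev**2))
    m3 = float(np.mean(dev**3))
    skew = 0.0 if m2 == 0.0 else m3 / m2**1.5
    if values.max() == values.min():
        ent = 0.0
    else:
        counts, _ = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
        p = counts[counts > 0] / values.size
        ent = float(-(p * np.log2(p)).sum())
    return {"mean": m, "variance": m2, "skewness": skew, "entropy": ent}


# ---------------------------------------------------------------------------
# gray-level co-occurrence matrix

#: distance-1 offsets (drow, dcol) for 0, 45, 90, 135 degrees
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_matrix(q: QuantizedImage) -> list[np.ndarray | None]:
    """Normalized symmetric co-occurrence matrix per direction.

    Only pairs with both pixels inside the mask are counted.  A direction with
    no valid pair yields ``None`` (excluded from feature averaging).
    """
    L = q.n_levels
    lev = np.where(q.mask, q.levels, 0)
    out: list[np.ndarray | None] = []
    nr, nc = lev.shape
    for dr, dc in DIRECTIONS:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = lev[r0:r1, c0:c1]
        b = lev[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            out.append(None)
            continue
        counts = np.zeros((L, L), dtype=np.float64)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
        counts = counts + counts.T  # symmetrize
        out.append(counts / counts.sum())
    return out


def glcm_features(matrices: list[np.ndarray | None]) -> dict[str, float]:
    """Six Haralick-style features averaged over the non-empty directions."""
    mats = [m for m in matrices if m is not None]
    if not mats:
        raise DegenerateInputError("no valid co-occurrence pairs in any direction")
    L = mats[0].shape[0]
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    per_dir = []
    for p in mats:
        mu = float((ii * p).sum())  # marginals equal by symmetry
        var = float(((ii - mu) ** 2 * p).sum())
        if var == 0.0:
            corr = 0.0
        else:
            corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
        nz = p[p > 0]
        per_dir.append(
            {
                "contrast": float((p * (ii - jj) ** 2).sum()),
                "correlation": corr,
                "energy": float((p**2).sum()),
                "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
                "entropy": float(-(nz * np.log2(nz)).sum()),
                "dissimilarity": float((p * np.abs(ii - jj)).sum()),
            }
        )
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# gray-level run-length matrix

def _runs_in_line(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal constant nonzero runs; 0 breaks runs."""
    n = line.size
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [n])))
    levels = line[starts]
    keep = levels > 0
    return levels[keep], lengths[keep]


def _scan_lines(lev: np.ndarray, direction: tuple[int, int]):
    """Yield the scan lines of a 2D level array along one of the 4 directions."""
    nr, nc = lev.shape
    if direction == (0, 1):  # 0 degrees: rows
        yield from lev
    elif direction == (-1, 0):  # 90 degrees: columns
        yield from lev.T
    elif direction == (-1, 1):  # 45 degrees: anti-diagonals, bottom-left to top-right
        fl = np.flipud(lev)
        for off in range(-(nr - 1), nc):
            yield np.diagonal(fl, offset=off)
    elif direction == (-1, -1):  # 135 degrees: main diagonals
        for off in range(-(nr - 1), nc):
            yield np.diagonal(lev, offset=off)
    else:  # pragma: no cover
        raise ValueError(f"unknown direction {direction}")


def glrm_matrix(q: QuantizedImage, direction: tuple[int, int]) -> np.ndarray:
    """Run-length counts r[g-1, l-1] for one direction (g level, l run length)."""
    lev = np.where(q.mask, q.levels, 0)
    max_len = max(lev.shape)
    r = np.zeros((q.n_levels, max_len), dtype=np.float64)
    for line in _scan_lines(lev, direction):
        g, l = _runs_in_line(np.ascontiguousarray(line))
        if g.size:
            np.add.at(r, (g - 1, l - 1), 1.0)
    return r


def _glrm_features_one(r: np.ndarray, n_pixels: int) -> dict[str, float] | None:
    n_r = r.sum()
    if n_r == 0:
        return None
    g = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "sre": float((r / l**2).sum() / n_r),
        "lre": float((r * l**2).sum() / n_r),
        "gln": float((r.sum(axis=1) ** 2).sum() / n_r),
        "rln": float((r.sum(axis=0) ** 2).sum() / n_r),
        "rp": float(n_r / n_pixels),
        "lgre": float((r / g**2).sum() / n_r),
        "hgre": float((r * g**2).sum() / n_r),
        "srlge": float((r / (g**2 * l**2)).sum() / n_r),
        "srhge": float((r * g**2 / l**2).sum() / n_r),
        "lrlge": float((r * l**2 / g**2).sum() / n_r),
        "lrhge": float((r * g**2 * l**2).sum() / n_r),
    }


def glrm_features(q: QuantizedImage) -> dict[str, float]:
    """Eleven run-emphasis features averaged over the 4 scan directions."""
    n_pixels = int(q.mask.sum())
    if n_pixels == 0:
        raise EmptyMaskError("empty mask in run-length computation")
    per_dir = []
    for d in DIRECTIONS:
        f = _glrm_features_one(glrm_matrix(q, d), n_pixels)
        if f is not None:
            per_dir.append(f)
    if not per_dir:
        raise DegenerateInputError("no runs found in any direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRM_NAMES}


# ---------------------------------------------------------------------------
# local binary patterns (riu2, P=8, R=1, square neighborhood)

# 8 neighbors in circular order starting at (0, +1), counter-clockwise
_LBP_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


def lbp_features(roi: RoiImage) -> dict[str, float]:
    """Normalized rotation-invariant uniform LBP histogram (10 bins).

    Bins u0..u8 hold uniform codes (at most 2 circular 0/1 transitions) by
    their number of set bits; the last bin collects all non-uniform codes.
    """
    inner = eroded_mask(roi.mask)
    if int(inner.sum()) < 16:
        raise DegenerateInputError("mask too small after erosion for LBP")
    px = roi.pixels
    center = px[1:-1, 1:-1]
    bits = np.stack(
        [
            (px[1 + dr : px.shape[0] - 1 + dr, 1 + dc : px.shape[1] - 1 + dc] >= center)
            for dr, dc in _LBP_OFFSETS
        ],
        axis=0,
    ).astype(np.int8)
    ones = bits.sum(axis=0)
    transitions = np.abs(bits - np.roll(bits, 1, axis=0)).sum(axis=0)
    labels = np.where(transitions <= 2, ones, 9)
    sel = labels[inner[1:-1, 1:-1]]
    hist = np.bincount(sel.ravel(), minlength=10).astype(np.float64)
    hist /= hist.sum()
    return {name: float(hist[k]) for k, name in enumerate(LBP_NAMES)}


# ---------------------------------------------------------------------------
# fractal analysis

def _binarize(roi: RoiImage) -> np.ndarray:
    vals = roi.masked_values
    if vals.max() == vals.min():
        return roi.mask.copy()  # flat ROI: the occupied set is the mask itself
    thr = threshold_otsu(vals)
    return roi.mask & (roi.pixels > thr)


def _box_counts(occ: np.ndarray, size: int) -> int:
    h, w = occ.shape
    ph, pw = (-h) % size, (-w) % size
    if ph or pw:
        occ = np.pad(occ, ((0, ph), (0, pw)))
    blocks = occ.reshape(occ.shape[0] // size, size, occ.shape[1] // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_features(roi: RoiImage, lacunarity_box: int = 4) -> dict[str, float]:
    """Box-counting dimension and gliding-box lacunarity of the Otsu-binarized ROI."""
    occ = _binarize(roi)
    if int(occ.sum()) < 2:
        warnings.warn("fewer than 2 occupied pixels after binarization; fractal features 0")
        return {"fd": 0.0, "lacunarity": 0.0}
    rows, cols = np.nonzero(occ)
    box = occ[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    max_dim = max(box.shape)
    sizes = []
    s = 1
    while s <= max_dim:
        sizes.append(s)
        s *= 2
    counts = np.array([_box_counts(box, s) for s in sizes], dtype=np.float64)
    slope = np.polyfit(np.log(1.0 / np.array(sizes)), np.log(counts), 1)[0]
    # lacunarity: gliding-box mass statistic at a fixed window size
    s_star = min(lacunarity_box, min(box.shape))
    win = np.lib.stride_tricks.sliding_window_view(box.astype(np.float64), (s_star, s_star))
    masses = win.sum(axis=(2, 3)).ravel()
    mean = masses.mean()
    lac = 0.0 if mean == 0 else float(masses.var() / mean**2 + 1.0)
    return {"fd": float(slope), "lacunarity": lac}


# ---------------------------------------------------------------------------
# shape

def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Area, exposed-edge perimeter, circularity, eccentricity, solidity, extent.

    Computed on the largest 4-connected component.  Perimeter is the count of
    pixel edges adjacent to background (4-connectivity), so a 3x3 square has
    perimeter 12.
    """
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise EmptyMaskError("empty mask in shape computation")
    labeled = measure.label(mask, connectivity=1)
    props = max(measure.regionprops(labeled), key=lambda p: p.area)
    comp = labeled == props.label
    area = float(comp.sum())
    adj = np.count_nonzero(comp[:, 1:] & comp[:, :-1]) + np.count_nonzero(
        comp[1:, :] & comp[:-1, :]
    )
    perimeter = 4.0 * area - 2.0 * adj
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": float(4.0 * np.pi * area / perimeter**2),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
    }


# ---------------------------------------------------------------------------
# assembly

def _quantize_values(values: np.ndarray, mask: np.ndarray, n_levels: int, what: str) -> QuantizedImage:
    norm = normalize_masked(values, mask, what=what)
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[mask] = np.minimum((norm[mask] * n_levels).astype(np.int64), n_levels - 1) + 1
    return QuantizedImage(levels=levels, n_levels=n_levels, mask=mask, source=what)


class FeatureExtractor:
    """Computes the frozen 152-feature inventory for one ROI.

    Derived images (gradient, wavelet bands, HoG) are computed lazily so the
    targeted :meth:`extract_named` path stays cheap.
    """

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config or FeatureConfig()

    # -- per-source helpers -------------------------------------------------
    def _sources(self, roi: RoiImage):
        cfg = self.config
        cache: dict[str, object] = {}

        def norm() -> RoiImage:
            if "norm" not in cache:
                cache["norm"] = normalize_roi(roi)
            return cache["norm"]  # type: ignore[return-value]

        def grad() -> RoiImage:
            if "grad" not in cache:
                cache["grad"] = gradient_image(norm())
            return cache["grad"]  # type: ignore[return-value]

        def bands() -> WaveletBands:
            if "bands" not in cache:
                cache["bands"] = haar_dwt(norm())
            return cache["bands"]  # type: ignore[return-value]

        def band_arr(source: str) -> tuple[np.ndarray, np.ndarray]:
            b = bands()
            arr = dict(b.items())[source]
            return arr, b.mask

        def values_mask(source: str) -> tuple[np.ndarray, np.ndarray]:
            if source == "base":
                n = norm()
                return n.pixels, n.mask
            if source == "grad":
                g = grad()
                return g.pixels, g.mask
            return band_arr(source)

        return norm, grad, bands, band_arr, values_mask

    def _family(self, roi: RoiImage, source: str, fam: str, helpers) -> dict[str, float]:
        norm, grad, _bands, band_arr, values_mask = helpers
        cfg = self.config
        if source == "hog":
            if fam != "fos":
                raise KeyError(f"hog has no family '{fam}'")
            return fos(hog_histogram(norm()).bin_values, n_bins=cfg.fos_bins)
        if fam == "fos":
            if source == "base":
                return fos(roi.masked_values, n_bins=cfg.fos_bins)  # raw intensities
            vals, mask = values_mask(source)
            return fos(vals[mask], n_bins=cfg.fos_bins)
        if fam == "power":
            vals, mask = band_arr(source)
            return {"mean_square": float(np.mean(vals[mask] ** 2))}
        if fam in ("glcm", "glrm"):
            vals, mask = values_mask(source)
            q = _quantize_values(vals, mask, cfg.n_levels, what=source)
            return glcm_features(glcm_matrix(q)) if fam == "glcm" else glrm_features(q)
        if fam == "lbp":
            return lbp_features(norm())
        if fam == "fractal":
            return fractal_features(norm(), lacunarity_box=cfg.lacunarity_box)
        if fam == "shape":
            return shape_features(roi.mask)
        raise KeyError(f"unknown family '{fam}' for source '{source}'")

    # -- public API ----------------------------------------------------------
    def extract(self, roi: RoiImage) -> dict[str, float]:
        """The full 152-entry feature vector, keys in canonical order."""
        helpers = self._sources(roi)
        out: dict[str, float] = {}
        done: dict[tuple[str, str], dict[str, float]] = {}
        for name in FEATURE_NAMES:
            source, fam, feat = name.split(".")
            key = (source, fam)
            if key not in done:
                try:
                    done[key] = self._family(roi, source, fam, helpers)
                except Exception as exc:
                    raise DegenerateInputError(
                        f"feature family {source}.{fam} failed for "
                        f"subject '{roi.subject_id}': {exc}"
                    ) from exc
            out[name] = done[key][feat]
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        if bad:
            raise DegenerateInputError(f"non-finite features for '{roi.subject_id}': {bad[:5]}")
        return out

    def extract_named(self, roi: RoiImage, names: list[str]) -> dict[str, float]:
        """Compute only the requested features (used by the cohort generator)."""
        helpers = self._sources(roi)
        out: dict[str, float] = {}
        done: dict[tuple[str, str], dict[str, float]] = {}
        for name in names:
            source, fam, feat = name.split(".")
            key = (source, fam)
            if key not in done:
                done[key] = self._family(roi, source, fam, helpers)
            out[name] = done[key][feat]
        return out


def extract_all(roi: RoiImage, config: FeatureConfig | None = None) -> dict[str, float]:
    """Convenience wrapper: the canonical 152-feature vector for one ROI."""
    return FeatureExtractor(config).extract(roi)


def extract_table(rois, config: FeatureConfig | None = None):
    """Stack feature vectors for a cohort into a DataFrame (rows = subjects)."""
    import pandas as pd

    ex = FeatureExtractor(config)
    rows = {roi.subject_id: ex.extract(roi) for roi in rois}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    table.index.name = "subject_id"
    return table
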