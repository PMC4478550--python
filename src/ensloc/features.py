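"""The 430-element morphological feature vector of a segmented cell.

Each cell is described by five feature families computed inside its mask:

* **area-shape** (46): size, contour and moment descriptors of the mask;
* **zernike** (49): magnitudes of Zernike moments |A_nm| of the GFP crop
  up to order 12, on the unit disc about the mask centroid, normalized by
  total mass (rotation- and contrast-invariant);
* **intensity** (60 per channel x 2): distributional, radial and edge
  statistics of the masked pixels;
* **texture** (208): 13 Haralick statistics of the masked gray-level
  co-occurrence matrix, 4 offsets x 2 distances x 2 channels;
* **location** (7): position of the cell within the field of view.

The registry (ordered feature list) is the single source of truth for
vector layout; its SHA-256 hash travels with every vector so classifiers
can refuse vectors extracted under a different layout.  Every feature
entry declares its intensity *scale degree*: the exponent d such that
multiplying the channel intensities by c multiplies the feature by c**d
(shape and location features have d = 0 by construction).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sstats
from skimage import measure

from .segment import GFP, RFP, CellRegion, Micrograph

ZERNIKE_ORDER = 12
HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)
GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))
GLCM_DISTANCES = (1, 2)
GLCM_LEVELS = 16

MIN_AREA = 9  # below this the vector is flagged unextractable


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    category: str  # area-shape | zernike | intensity | texture | location
    channel: str  # GFP | RFP | none
    scale_degree: int = 0
    params: tuple = ()


@dataclass(frozen=True)
class FeatureRegistry:
    entries: tuple[FeatureEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def hash(self) -> str:
        text = "\n".join(
            f"{e.name}|{e.category}|{e.channel}|{e.scale_degree}" for e in self.entries
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def indices(self, category: str | None = None, channel: str | None = None) -> np.ndarray:
        return np.array(
            [
                i
                for i, e in enumerate(self.entries)
                if (category is None or e.category == category)
                and (channel is None or e.channel == channel)
            ],
            dtype=int,
        )


@dataclass
class FeatureVector:
    """Feature values of one cell, aligned to a registry."""

    values: np.ndarray
    registry_hash: str
    cell_ref: tuple = ()
    extractable: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


# ---------------------------------------------------------------------------
# registry construction

_SHAPE_NAMES = (
    "area",
    "perimeter",
    "convex_area",
    "convex_deficiency",
    "solidity",
    "extent",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "equivalent_diameter",
    "form_factor",
    "compactness",
    "roundness",
    "feret_diameter_max",
    "euler_number",
    *(f"hu_moment_{i}" for i in range(1, 8)),
    "radius_mean",
    "radius_std",
    "radius_min",
    "radius_max",
    "radius_cv",
    "radius_iqr",
    "bbox_height",
    "bbox_width",
    "bbox_aspect",
    "perimeter_area_ratio",
    "nmu_20",
    "nmu_11",
    "nmu_02",
    "nmu_30",
    "nmu_21",
    "nmu_12",
    "nmu_03",
    "edt_max",
    "edt_mean",
    "edt_std",
    "centroid_bbox_offset_r",
    "centroid_bbox_offset_c",
    "interior_fraction",
)

# (name, scale degree)
_INTENSITY_NAMES: tuple[tuple[str, int], ...] = (
    ("integrated", 1),
    ("mean", 1),
    ("median", 1),
    ("std", 1),
    ("mad", 1),
    ("min", 1),
    ("max", 1),
    ("range", 1),
    ("cv", 0),
    ("skewness", 0),
    ("kurtosis", 0),
    ("q01", 1),
    ("q05", 1),
    ("q10", 1),
    ("q25", 1),
    ("q75", 1),
    ("q90", 1),
    ("q99", 1),
    ("iqr", 1),
    ("entropy", 0),
    ("edge_mean", 1),
    ("edge_integrated", 1),
    ("interior_mean", 1),
    ("edge_interior_ratio", 0),
    ("mass_displacement", 0),
    *((f"radial_mass_frac_{i}", 0) for i in range(1, 5)),
    *((f"radial_mean_{i}", 1) for i in range(1, 5)),
    *((f"radial_std_{i}", 1) for i in range(1, 5)),
    ("frac_above_mean", 0),
    ("frac_above_2mean", 0),
    ("top5_mean", 1),
    ("top10_mass_frac", 0),
    ("n_local_maxima", 0),
    ("max_to_mean", 0),
    ("gradient_mean", 1),
    ("gradient_std", 1),
    ("gradient_max", 1),
    ("bright_area_frac", 0),
    ("bright_object_count", 0),
    *((f"hist_frac_{i}", 0) for i in range(1, 9)),
    ("weighted_centroid_offset_r", 0),
    ("weighted_centroid_offset_c", 0),
    ("radial_second_moment", 0),
    ("quartile_dispersion", 0),
)

_LOCATION_NAMES = (
    "centroid_x_norm",
    "centroid_y_norm",
    "dist_to_border",
    "dist_to_border_norm",
    "border_touch_fraction",
    "offcenter_radius_norm",
    "area_fraction_of_image",
)


def _zernike_nm_pairs(max_order: int) -> list[tuple[int, int]]:
    return [
        (n, m)
        for n in range(max_order + 1)
        for m in range(n % 2, n + 1, 2)
    ]


@lru_cache(maxsize=1)
def default_registry() -> FeatureRegistry:
    """The canonical 430-feature registry (order fixed)."""
    entries: list[FeatureEntry] = []
    for name in _SHAPE_NAMES:
        entries.append(FeatureEntry(f"shape_{name}", "area-shape", "none", 0))
    for n, m in _zernike_nm_pairs(ZERNIKE_ORDER):
        entries.append(FeatureEntry(f"zernike_{n}_{m}", "zernike", GFP, 0, (n, m)))
    for ch in (GFP, RFP):
        for name, deg in _INTENSITY_NAMES:
            entries.append(FeatureEntry(f"intensity_{ch.lower()}_{name}", "intensity", ch, deg))
    for ch in (GFP, RFP):
        for dist in GLCM_DISTANCES:
            for oi, off in enumerate(GLCM_OFFSETS):
                for stat in HARALICK_NAMES:
                    entries.append(
                        FeatureEntry(
                            f"texture_{ch.lower()}_d{dist}_o{oi}_{stat}",
                            "texture",
                            ch,
                            0,
                            (dist, off, stat),
                        )
                    )
    for name in _LOCATION_NAMES:
        entries.append(FeatureEntry(f"location_{name}", "location", "none", 0))
    return FeatureRegistry(tuple(entries))


# ---------------------------------------------------------------------------
# Zernike moments


@lru_cache(maxsize=256)
def _zernike_radial_coeffs(n: int, m: int) -> tuple[tuple[int, float], ...]:
    """Coefficients (power, coeff) of the radial polynomial R_nm."""
    coeffs = []
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        coeffs.append((n - 2 * s, float(c)))
    return tuple(coeffs)


def zernike_features(
    cell_image: np.ndarray,
    max_order: int = ZERNIKE_ORDER,
    radius: float | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Zernike moment magnitudes |A_nm| of a masked crop.

    The crop is mapped to the unit disc of ``radius`` pixels about the
    mask's intensity-bearing centroid and normalized by total mass, so
    the magnitudes are invariant to rotation and to uniform intensity
    scaling.  Returns one value per (n, m) with n <= max_order,
    m >= 0, n - m even, in the fixed (n asc, m asc) order.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    img = np.asarray(cell_image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty crop")
    if mask is not None:
        img = np.where(mask, img, 0.0)
    total = img.sum()
    pairs = _zernike_nm_pairs(max_order)
    if total <= 0:
        return np.zeros(len(pairs))

    rr, cc = np.nonzero(img > 0) if mask is None else np.nonzero(mask)
    vals = img[rr, cc]
    cy = (vals * rr).sum() / vals.sum() if mask is None else rr.mean()
    cx = (vals * cc).sum() / vals.sum() if mask is None else cc.mean()
    if radius is None:
        radius = float(np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2).max()) or 1.0
    if radius <= 0:
        raise ValueError("radius must be > 0")

    rho = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2) / radius
    inside = rho <= 1.0
    rho = rho[inside]
    theta = np.arctan2(rr[inside] - cy, cc[inside] - cx)
    v = img[rr[inside], cc[inside]] / total

    out = np.empty(len(pairs))
    rho_pows = {p: rho**p for p in range(max_order + 1)}
    for i, (n, m) in enumerate(pairs):
        radial = np.zeros_like(rho)
        for p, c in _zernike_radial_coeffs(n, m):
            radial += c * rho_pows[p]
        a = (n + 1) / math.pi * np.sum(v * radial * np.exp(-1j * m * theta))
        out[i] = abs(a)
    return out


# ---------------------------------------------------------------------------
# Haralick texture


def masked_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int],
    distance: int,
    levels: int = GLCM_LEVELS,
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    Pixels are quantized to ``levels`` bins over the masked min-max range
    (making the GLCM invariant to uniform intensity scaling); only pixel
    pairs with *both* ends inside the mask are counted.
    """
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=np.int32)
    if hi > lo:
        q[mask] = np.minimum(
            ((image[mask] - lo) / (hi - lo) * levels).astype(np.int32), levels - 1
        )
    dr, dc = offset[0] * distance, offset[1] * distance
    h, w = image.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    valid = mask[src] & mask[dst]
    i = q[src][valid]
    j = q[dst][valid]
    glcm = np.zeros((levels, levels))
    np.add.at(glcm, (i, j), 1.0)
    glcm += glcm.T  # symmetric
    total = glcm.sum()
    if total > 0:
        glcm /= total
    return glcm


def haralick_stats(glcm: np.ndarray) -> np.ndarray:
    """The 13 classic Haralick statistics of a normalized GLCM."""
    L = glcm.shape[0]
    eps = 1e-12
    i = np.arange(L)[:, None].astype(float)
    j = np.arange(L)[None, :].astype(float)
    p = glcm
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = (np.arange(L) * px).sum()
    my = (np.arange(L) * py).sum()
    sx = math.sqrt(max(((np.arange(L) - mx) ** 2 * px).sum(), 0.0))
    sy = math.sqrt(max(((np.arange(L) - my) ** 2 * py).sum(), 0.0))

    asm = (p**2).sum()
    contrast = (((i - j) ** 2) * p).sum()
    if sx > eps and sy > eps:
        correlation = (((i - mx) * (j - my) * p).sum()) / (sx * sy)
    else:
        correlation = 0.0
    variance = (((i - mx) ** 2) * p).sum()
    idm = (p / (1.0 + (i - j) ** 2)).sum()

    k_sum = np.arange(2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel(), p.ravel())
    sum_average = (k_sum * p_sum).sum()
    sum_variance = (((k_sum - sum_average) ** 2) * p_sum).sum()
    sum_entropy = -(p_sum[p_sum > eps] * np.log(p_sum[p_sum > eps])).sum()

    entropy = -(p[p > eps] * np.log(p[p > eps])).sum()

    k_diff = np.arange(L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel(), p.ravel())
    diff_mean = (k_diff * p_diff).sum()
    difference_variance = (((k_diff - diff_mean) ** 2) * p_diff).sum()
    difference_entropy = -(p_diff[p_diff > eps] * np.log(p_diff[p_diff > eps])).sum()

    hx = -(px[px > eps] * np.log(px[px > eps])).sum()
    hy = -(py[py > eps] * np.log(py[py > eps])).sum()
    pxy = px[:, None] * py[None, :]
    hxy1 = -(p * np.log(pxy + eps)).sum()
    hxy2 = -(pxy * np.log(pxy + eps)).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > eps else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - entropy))
    imc2 = math.sqrt(max(arg, 0.0))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


# ---------------------------------------------------------------------------
# per-family extractors


def _finite(x: float) -> float:
    return float(x) if np.isfinite(x) else 0.0


def _shape_features(mask: np.ndarray) -> np.ndarray:
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(props.perimeter) or 1.0
    hull_area = float(props.area_convex)
    contours = measure.find_contours(np.pad(mask.astype(float), 1), 0.5)
    cy, cx = props.centroid
    radii = np.array([1.0])
    if contours:
        pts = contours[0] - 1.0
        radii = np.sqrt((pts[:, 0] - cy) ** 2 + (pts[:, 1] - cx) ** 2)
    edt = ndi.distance_transform_edt(mask)
    edt_vals = edt[mask]
    h, w = mask.shape
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    nmu = props.moments_normalized
    inner = ndi.binary_erosion(mask, iterations=2, border_value=0)
    vals = [
        area,
        perim,
        hull_area,
        (hull_area - area) / hull_area if hull_area else 0.0,
        float(props.solidity),
        float(props.extent),
        float(props.eccentricity),
        major,
        minor,
        major / minor if minor else 0.0,
        float(props.equivalent_diameter_area),
        4.0 * math.pi * area / perim**2,
        perim**2 / (4.0 * math.pi * area),
        4.0 * area / (math.pi * major**2) if major else 0.0,
        float(props.feret_diameter_max),
        float(props.euler_number),
        *[float(x) for x in props.moments_hu],
        float(radii.mean()),
        float(radii.std()),
        float(radii.min()),
        float(radii.max()),
        float(radii.std() / radii.mean()) if radii.mean() else 0.0,
        float(np.quantile(radii, 0.75) - np.quantile(radii, 0.25)),
        float(h),
        float(w),
        h / w if w else 0.0,
        perim / area,
        float(nmu[2, 0]),
        float(nmu[1, 1]),
        float(nmu[0, 2]),
        float(nmu[3, 0]),
        float(nmu[2, 1]),
        float(nmu[1, 2]),
        float(nmu[0, 3]),
        float(edt_vals.max()),
        float(edt_vals.mean()),
        float(edt_vals.std()),
        float(cy - (h - 1) / 2.0),
        float(cx - (w - 1) / 2.0),
        float(inner.sum() / area),
    ]
    return np.array([_finite(v) for v in vals])


def _intensity_features(crop: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = crop[mask]
    n = v.size
    total = float(v.sum())
    mean = float(v.mean())
    std = float(v.std())
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    vmin, vmax = float(v.min()), float(v.max())
    qs = np.quantile(v, [0.01, 0.05, 0.10, 0.25, 0.75, 0.90, 0.99])
    iqr = float(qs[4] - qs[3])

    # histogram over the cell's own range: scale-invariant
    if vmax > vmin:
        hist, _ = np.histogram(v, bins=32, range=(vmin, vmax))
        p = hist / n
        entropy = float(-(p[p > 0] * np.log(p[p > 0])).sum())
        hist8, _ = np.histogram(v, bins=8, range=(vmin, vmax))
        hist8 = hist8 / n
    else:
        entropy = 0.0
        hist8 = np.zeros(8)
        hist8[0] = 1.0

    inner = ndi.binary_erosion(mask, iterations=2, border_value=0)
    edge = mask & ~inner
    edge_vals = crop[edge] if edge.any() else np.zeros(1)
    inner_vals = crop[inner] if inner.any() else np.zeros(1)
    edge_mean = float(edge_vals.mean())
    inner_mean = float(inner_vals.mean())

    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    if total > 0:
        wy = (crop[rr, cc] * rr).sum() / total
        wx = (crop[rr, cc] * cc).sum() / total
    else:
        wy, wx = cy, cx
    mass_disp = math.hypot(wy - cy, wx - cx)

    r = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    rmax = r.max() or 1.0
    pix = crop[rr, cc]
    # radial distribution about the signal's own center of mass, scaled by
    # the cell radius: separates e.g. a small perinuclear ring from a large
    # vacuolar rim regardless of where the structure sits in the cell
    rw = np.sqrt((rr - wy) ** 2 + (cc - wx) ** 2)
    rn = np.minimum(rw / rmax, 1.0)
    radial_frac = np.zeros(4)
    radial_mean = np.zeros(4)
    radial_std = np.zeros(4)
    for k in range(4):
        sel = (rn >= k * 0.25) & (rn < (k + 1) * 0.25 if k < 3 else rn <= 1.0)
        if sel.any():
            radial_frac[k] = pix[sel].sum() / total if total > 0 else 0.0
            radial_mean[k] = pix[sel].mean()
            radial_std[k] = pix[sel].std()

    thr = 0.5 * vmax
    bright = mask & (crop >= thr) if vmax > 0 else np.zeros_like(mask)
    n_bright, _ = (0, None)
    if bright.any():
        lab, n_bright = ndi.label(bright, structure=np.ones((3, 3)))
    # local maxima above half-max
    if vmax > 0:
        mx = ndi.maximum_filter(crop, size=3)
        peaks = mask & (crop == mx) & (crop >= thr)
        lab_p, n_peaks = ndi.label(peaks, structure=np.ones((3, 3)))
    else:
        n_peaks = 0

    gy, gx = np.gradient(crop)
    gmag = np.hypot(gy, gx)[mask]

    k_sorted = np.sort(v)[::-1]
    n5 = max(1, int(round(0.05 * n)))
    n10 = max(1, int(round(0.10 * n)))
    top5_mean = float(k_sorted[:n5].mean())
    top10_mass = float(k_sorted[:n10].sum() / total) if total > 0 else 0.0

    second_moment = float((pix * rn**2).sum() / total) if total > 0 else 0.0

    vals = [
        total,
        mean,
        med,
        std,
        mad,
        vmin,
        vmax,
        vmax - vmin,
        std / mean if mean else 0.0,
        float(sstats.skew(v)) if std > 0 else 0.0,
        float(sstats.kurtosis(v)) if std > 0 else 0.0,
        *[float(q) for q in qs],
        iqr,
        entropy,
        edge_mean,
        float(edge_vals.sum()),
        inner_mean,
        edge_mean / inner_mean if inner_mean else 0.0,
        mass_disp,
        *radial_frac,
        *radial_mean,
        *radial_std,
        float((v > mean).mean()),
        float((v > 2 * mean).mean()),
        top5_mean,
        top10_mass,
        float(n_peaks),
        vmax / mean if mean else 0.0,
        float(gmag.mean()),
        float(gmag.std()),
        float(gmag.max()),
        float(bright.sum() / n),
        float(n_bright),
        *[float(x) for x in hist8],
        float(wy - cy) / rmax,
        float(wx - cx) / rmax,
        second_moment,
        iqr / (qs[4] + qs[3]) if (qs[4] + qs[3]) else 0.0,
    ]
    return np.array([_finite(x) for x in vals])


def _texture_features(crop: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = []
    for dist in GLCM_DISTANCES:
        for off in GLCM_OFFSETS:
            glcm = masked_glcm(crop, mask, off, dist)
            if glcm.sum() == 0:
                out.append(np.zeros(len(HARALICK_NAMES)))
            else:
                out.append(haralick_stats(glcm))
    return np.concatenate(out)


def _location_features(
    mask_full_bbox: tuple[int, int, int, int],
    mask: np.ndarray,
    image_shape: tuple[int, int],
) -> np.ndarray:
    r0, c0, r1, c1 = mask_full_bbox
    h, w = image_shape
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean() + r0, cc.mean() + c0
    dist_border = min(cy, cx, h - 1 - cy, w - 1 - cx)
    border_px = 0
    if r0 == 0:
        border_px += int(mask[0].sum())
    if r1 == h:
        border_px += int(mask[-1].sum())
    if c0 == 0:
        border_px += int(mask[:, 0].sum())
    if c1 == w:
        border_px += int(mask[:, -1].sum())
    perim_est = 2 * (mask.shape[0] + mask.shape[1])
    offr = cy - (h - 1) / 2.0
    offc = cx - (w - 1) / 2.0
    halfdiag = math.hypot(h / 2.0, w / 2.0)
    vals = [
        cx / w,
        cy / h,
        float(dist_border),
        float(dist_border) / (min(h, w) / 2.0),
        border_px / perim_est,
        math.hypot(offr, offc) / halfdiag,
        mask.sum() / (h * w),
    ]
    return np.array([_finite(x) for x in vals])


# ---------------------------------------------------------------------------
# public extraction


def extract_features(
    region: CellRegion,
    gfp: Micrograph,
    rfp: Micrograph,
    registry: FeatureRegistry | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one segmented cell.

    Intensity and texture features are computed within the mask only.
    A degenerate mask (area < 9 px) yields a zero vector flagged
    ``extractable=False`` so the cell can be excluded downstream.
    """
    registry = registry or default_registry()
    if gfp.channel != GFP or rfp.channel != RFP:
        raise ValueError("extract_features expects (region, GFP, RFP) channels")
    ref = (gfp.screen_id, gfp.strain_id, gfp.field_index, region.object_id)
    if region.area < MIN_AREA:
        return FeatureVector(
            np.zeros(len(registry)), registry.hash, ref, extractable=False
        )
    r0, c0, r1, c1 = region.bbox
    mask = region.mask
    gcrop = gfp.pixels[r0:r1, c0:c1]
    rcrop = rfp.pixels[r0:r1, c0:c1]

    parts = [
        _shape_features(mask),
        zernike_features(np.where(mask, gcrop, 0.0), ZERNIKE_ORDER, mask=mask),
        _intensity_features(gcrop, mask),
        _intensity_features(rcrop, mask),
        _texture_features(gcrop, mask),
        _texture_features(rcrop, mask),
        _location_features(region.bbox, mask, gfp.shape),
    ]
    values = np.concatenate(parts)
    if len(values) != len(registry):
        raise RuntimeError(
            f"extractor produced {len(values)} values for a "
            f"{len(registry)}-entry registry"
        )
    values[~np.isfinite(values)] = 0.0
    return FeatureVector(values, registry.hash, ref)


def extract_from_crop(crop, registry: FeatureRegistry | None = None) -> FeatureVector:
    """Feature vector of a phantom :class:`~ensloc.phantom.TrainingCrop`."""
    from .segment import measure_region, segment_cells

    registry = registry or default_registry()
    mask = crop.mask
    rr, cc = np.nonzero(mask)
    if rr.size < MIN_AREA:
        return FeatureVector(np.zeros(len(registry)), registry.hash, extractable=False)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    sub = mask[r0:r1, c0:c1]
    region = CellRegion(
        object_id=1,
        mask=sub,
        bbox=(r0, c0, r1, c1),
        centroid=(float(cc.mean()), float(rr.mean())),
        area=int(sub.sum()),
    )
    gfp_m = Micrograph(crop.gfp, GFP)
    rfp_m = Micrograph(crop.rfp, RFP)
    measure_region(region, gfp_m)
    measure_region(region, rfp_m)
    return extract_features(region, gfp_m, rfp_m, registry)


def feature_matrix(
    vectors: list[FeatureVector],
) -> tuple[np.ndarray, str]:
    """Stack vectors into a (cells x features) matrix; verifies one registry."""
    hashes = {v.registry_hash for v in vectors}
    if len(hashes) != 1:
        raise ValueError("vectors come from different registries")
    return np.vstack([v.values for v in vectors]), hashes.pop()


def write_feature_table(path, vectors: list[FeatureVector], registry: FeatureRegistry | None = None) -> None:
    """TSV of the feature matrix with a header comment carrying the registry hash."""
    registry = registry or default_registry()
    X, rh = feature_matrix(vectors)
    if rh != registry.hash:
        raise ValueError("vectors do not match the given registry")
    with open(path, "w") as fh:
        fh.write(f"# registry_hash={rh}\n")
        fh.write("cell_ref\t" + "\t".join(registry.names) + "\n")
        for v in vectors:
            ref = ":".join(str(x) for x in v.cell_ref) or "-"
            fh.write(ref + "\t" + "\t".join(f"{x:.6g}" for x in v.values) + "\n")
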