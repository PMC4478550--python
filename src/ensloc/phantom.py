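"""Synthetic two-channel yeast micrograph generator ("phantoms").

Real screens image log-phase budding yeast expressing a cytoplasmic red
marker (for segmentation) and one GFP-tagged protein per strain.  This
module emulates such fields: ellipsoidal mother cells with optional buds,
a red channel filled uniformly inside every live cell, and a green channel
carrying one of 16 canonical localization patterns per cell (diffuse
cytoplasm, nuclear disc, boundary ring, puncta, budneck band, ...).  Dead
cells (shriveled, high-texture red blobs) and "ghost" objects (dim red
background blobs containing no cell) emulate the artifact classes that the
quality-control classifiers must remove.  Every rendered object comes with
ground truth, so the full classification and scoring stack is trainable
and testable without real data.

Patterns are parameterized through :data:`PATTERN_PARAMS` so that classes
can be made deliberately confusable (e.g. endosome vs Golgi puncta sizes)
for stress tests.  All randomness flows from explicit integer seeds;
identical spec + seed gives bit-identical images and truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .segment import GFP, RFP, Micrograph

#: The 16 localization classes, in the fixed order used by assignment
#: vectors and localization profiles throughout the package.
CLASSES: tuple[str, ...] = (
    "cytoplasm",
    "endosome",
    "ER",
    "Golgi",
    "mitochondria",
    "nuclear periphery",
    "nucleus",
    "nucleolus",
    "peroxisome",
    "vacuole/vacuolar membrane",
    "cortical patches",
    "bud",
    "budneck",
    "budsite",
    "cell periphery",
    "spindle pole",
)

#: Classes whose defining structure exists only on budded cells.
BUDDED_ONLY_CLASSES = frozenset({"bud", "budneck", "budsite"})

UNBUDDED = "unbudded"
SMALL_BUDDED = "small-budded"
LARGE_BUDDED = "large/medium-budded"

#: Per-class pattern parameters (pixel units).  Edit copies of this table
#: to stress-test confusable classes.
PATTERN_PARAMS: dict[str, dict] = {
    "cytoplasm": {},
    "endosome": {"n_puncta": (3, 6), "radius": 1.2},
    "ER": {"ring_width": 1.6, "cortical_amp": 0.7},
    "Golgi": {"n_puncta": (3, 8), "radius": 2.0},
    "mitochondria": {"n_branches": (2, 4), "thickness": 1.4, "steps": 26},
    "nuclear periphery": {"ring_width": 1.6},
    "nucleus": {},
    "nucleolus": {},
    "peroxisome": {"n_puncta": (2, 4), "radius": 1.0},
    "vacuole/vacuolar membrane": {"p_membrane": 0.5, "rim_width": 2.0, "lumen_haze": 0.3},
    "cortical patches": {"n_puncta": (6, 12), "radius": 1.3},
    "bud": {},
    "budneck": {"half_width": 2.0},
    "budsite": {"radius": 1.6},
    "cell periphery": {"ring_width": 2.0},
    "spindle pole": {"n_dots": None, "radius": 1.3, "separation": (4.0, 12.0)},
}

#: Blur applied to noise-free patterns (optics point-spread stand-in).
_PSF_SIGMA = 0.6


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without mask overlap."""


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-free ellipse: center (row, col), semi-axes, rotation."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float = 0.0

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def contains(self, rr: np.ndarray, cc: np.ndarray, scale: float = 1.0) -> np.ndarray:
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        u = dr * ca + dc * sa
        v = -dr * sa + dc * ca
        a, b = self.semi_axes
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0

    def boundary_point(self, theta: float) -> tuple[float, float]:
        a, b = self.semi_axes
        u, v = a * math.cos(theta), b * math.sin(theta)
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        return (self.center[0] + u * ca - v * sa, self.center[1] + u * sa + v * ca)


@dataclass(frozen=True)
class CellGeometry:
    """Mother ellipse plus optional bud ellipse."""

    mother: Ellipse
    bud: Ellipse | None = None

    @property
    def budded(self) -> bool:
        return self.bud is not None

    @property
    def cycle_stage(self) -> str:
        if self.bud is None:
            return UNBUDDED
        ratio = self.bud.area / self.mother.area
        return SMALL_BUDDED if ratio < 0.4 else LARGE_BUDDED

    @property
    def center(self) -> tuple[float, float]:
        return self.mother.center

    def radius_bound(self) -> float:
        """Radius of a disc around the mother center covering the cell."""
        r = max(self.mother.semi_axes)
        if self.bud is not None:
            d = math.dist(self.mother.center, self.bud.center)
            r = max(r, d + max(self.bud.semi_axes))
        return r + 1.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        m = self.mother.contains(rr, cc)
        if self.bud is not None:
            m |= self.bud.contains(rr, cc)
        return m

    def shifted(self, dr: float, dc: float) -> "CellGeometry":
        def mv(e: Ellipse) -> Ellipse:
            return replace(e, center=(e.center[0] + dr, e.center[1] + dc))

        return CellGeometry(mv(self.mother), mv(self.bud) if self.bud else None)


def sample_geometry(
    rng: np.random.Generator,
    budded: bool,
    center: tuple[float, float] = (0.0, 0.0),
) -> CellGeometry:
    """Draw a random cell geometry.

    Mother axes span 18-30 px (semi-axes 9-15); buds cover 25-75% of the
    mother area and are attached with substantial overlap so the
    mother-bud neck is wide (a single segmentable object).
    """
    a = rng.uniform(9.0, 15.0)
    b = a * rng.uniform(0.75, 1.0)
    angle = rng.uniform(0, math.pi)
    mother = Ellipse(center, (a, b), angle)
    bud = None
    if budded:
        frac = rng.uniform(0.25, 0.75)
        scale = math.sqrt(frac)
        ba, bb = a * scale, b * scale
        theta = rng.uniform(0, 2 * math.pi)
        pr, pc = mother.boundary_point(theta)
        # place bud center between the attachment point and its own radius,
        # pulled inward so the ellipses overlap and the neck is wide
        direction = math.atan2(pr - center[0], pc - center[1])
        reach = 0.50 * min(ba, bb)
        bud = Ellipse(
            (pr + reach * math.sin(direction), pc + reach * math.cos(direction)),
            (ba, bb),
            angle=direction,
        )
    return CellGeometry(mother, bud)


# ---------------------------------------------------------------------------
# pattern rendering


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0 : shape[0], 0 : shape[1]]


def _erode(mask: np.ndarray, px: int) -> np.ndarray:
    if px <= 0:
        return mask
    return ndi.binary_erosion(mask, iterations=px, border_value=0)


def _ring(mask: np.ndarray, width: float) -> np.ndarray:
    """Band of ``width`` px just inside the mask boundary."""
    inner = _erode(mask, max(1, int(round(width))))
    return mask & ~inner


def _puncta(
    shape: tuple[int, int],
    points: list[tuple[float, float]],
    radius: float,
) -> np.ndarray:
    rr, cc = _grid(shape)
    out = np.zeros(shape, dtype=np.float64)
    for pr, pc in points:
        d2 = (rr - pr) ** 2 + (cc - pc) ** 2
        out += np.exp(-d2 / (2.0 * radius**2))
    return np.clip(out, 0.0, 1.0)


def _interior_points(
    rng: np.random.Generator, mask: np.ndarray, n: int, min_sep: float = 3.0
) -> list[tuple[float, float]]:
    coords = np.argwhere(mask)
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < 50 * n + 50:
        tries += 1
        r, c = coords[rng.integers(len(coords))]
        if all((r - p[0]) ** 2 + (c - p[1]) ** 2 >= min_sep**2 for p in pts):
            pts.append((float(r), float(c)))
    return pts


def _organelle_axis(geom: CellGeometry) -> float:
    """Direction (radians) of the nucleus offset within the mother.

    Budded cells orient the nucleus toward the bud neck, as in mitosis;
    the vacuole sits opposite, keeping its rim away from the neck.
    """
    if geom.bud is not None:
        dr = geom.bud.center[0] - geom.mother.center[0]
        dc = geom.bud.center[1] - geom.mother.center[1]
        return math.atan2(dr, dc)
    return geom.mother.angle


def _nucleus_ellipse(geom: CellGeometry) -> Ellipse:
    """Nuclear disc: ~30% of the mother radius, slightly off-center."""
    a, b = geom.mother.semi_axes
    r = 0.32 * min(a, b)
    off = 0.22 * min(a, b)
    ang = _organelle_axis(geom)
    return Ellipse(
        (geom.mother.center[0] + off * math.sin(ang), geom.mother.center[1] + off * math.cos(ang)),
        (r, r),
    )


def _vacuole_ellipse(geom: CellGeometry) -> Ellipse:
    """Vacuole: large disc (over half the cell radius) opposite the nucleus."""
    a, b = geom.mother.semi_axes
    r = 0.55 * min(a, b)
    off = 0.25 * min(a, b)
    ang = _organelle_axis(geom)
    return Ellipse(
        (geom.mother.center[0] - off * math.sin(ang), geom.mother.center[1] - off * math.cos(ang)),
        (r, r),
    )


def class_region_mask(
    class_label: str, geometry: CellGeometry, shape: tuple[int, int]
) -> np.ndarray:
    """The region of the cell that defines ``class_label``'s pattern.

    Used by containment checks: a rendered pattern should deposit at
    least 85% of its mass inside this mask.  Regions carry a ~2 px margin
    for the point-spread blur.
    """
    rr, cc = _grid(shape)
    cell = geometry.mask(shape)
    nuc = _nucleus_ellipse(geometry)
    pad = lambda m: ndi.binary_dilation(m, iterations=2)  # noqa: E731

    if class_label == "cytoplasm":
        return pad(cell & ~nuc.contains(rr, cc, scale=0.8))
    if class_label == "nucleus":
        return pad(nuc.contains(rr, cc))
    if class_label == "nucleolus":
        return pad(nuc.contains(rr, cc))
    if class_label == "nuclear periphery":
        return pad(nuc.contains(rr, cc, scale=1.4) & ~nuc.contains(rr, cc, scale=0.55))
    if class_label == "ER":
        peri = nuc.contains(rr, cc, scale=1.6) & ~nuc.contains(rr, cc, scale=0.5)
        return pad(peri | _ring(cell, 4))
    if class_label == "vacuole/vacuolar membrane":
        return pad(_vacuole_ellipse(geometry).contains(rr, cc, scale=1.25))
    if class_label in ("endosome", "Golgi", "peroxisome", "mitochondria", "spindle pole"):
        return pad(cell)
    if class_label == "cortical patches":
        return pad(_ring(cell, 4))
    if class_label == "cell periphery":
        return pad(_ring(cell, 3))
    if class_label == "bud":
        if geometry.bud is None:
            raise ValueError("bud region undefined for unbudded geometry")
        return pad(geometry.bud.contains(rr, cc))
    if class_label == "budneck":
        if geometry.bud is None:
            raise ValueError("budneck region undefined for unbudded geometry")
        neck = geometry.mother.contains(rr, cc, scale=1.12) & geometry.bud.contains(
            rr, cc, scale=1.12
        )
        return pad(neck & cell)
    if class_label == "budsite":
        return pad(_ring(cell, 4))
    raise ValueError(f"unknown localization class {class_label!r}")


def render_pattern(
    class_label: str,
    geometry: CellGeometry,
    expression: float,
    seed: int,
    shape: tuple[int, int] | None = None,
    params: dict | None = None,
) -> np.ndarray:
    """Render the noise-free GFP image of one cell.

    The returned image is non-negative with pixel value ``expression``
    times a unit-amplitude pattern density, lightly blurred by a fixed
    point-spread sigma.  Zero expression gives an all-zero image.
    Budneck, bud, budsite, and the two-dot spindle-pole pattern require
    budded geometry.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown localization class {class_label!r}")
    if expression < 0:
        raise ValueError("expression must be non-negative")
    p = dict(PATTERN_PARAMS[class_label])
    if params:
        p.update(params)
    if class_label in BUDDED_ONLY_CLASSES and not geometry.budded:
        raise ValueError(f"{class_label!r} pattern requires budded geometry")
    if class_label == "spindle pole" and p.get("n_dots") == 2 and not geometry.budded:
        raise ValueError("two-dot spindle-pole pattern requires budded geometry")

    if shape is None:
        r = geometry.radius_bound()
        cr, cc_ = geometry.center
        size = int(math.ceil(2 * r + 8))
        shape = (size, size)
        geometry = geometry.shifted(size / 2 - cr, size / 2 - cc_)

    rng = np.random.default_rng(seed)
    rr, cc = _grid(shape)
    cell = geometry.mask(shape)
    nuc = _nucleus_ellipse(geometry)
    density = np.zeros(shape, dtype=np.float64)

    if class_label == "cytoplasm":
        density = (cell & ~nuc.contains(rr, cc)).astype(float)
    elif class_label == "nucleus":
        density = nuc.contains(rr, cc).astype(float)
    elif class_label == "nucleolus":
        # crescent: nuclear disc minus a shifted copy of itself
        shift = 0.8 * nuc.semi_axes[0]
        moved = replace(nuc, center=(nuc.center[0], nuc.center[1] + shift))
        density = (nuc.contains(rr, cc) & ~moved.contains(rr, cc)).astype(float)
    elif class_label == "nuclear periphery":
        w = p["ring_width"]
        density = (nuc.contains(rr, cc, scale=1.15) & ~nuc.contains(rr, cc, scale=1.15 - w / max(nuc.semi_axes))).astype(float)
    elif class_label == "ER":
        w = p["ring_width"]
        peri = nuc.contains(rr, cc, scale=1.35) & ~nuc.contains(rr, cc, scale=1.35 - w / max(nuc.semi_axes))
        cortical = _ring(cell, int(round(w)))
        density = peri.astype(float) + p["cortical_amp"] * cortical.astype(float)
    elif class_label == "vacuole/vacuolar membrane":
        vac = _vacuole_ellipse(geometry)
        inside = vac.contains(rr, cc) & cell
        if rng.random() < p["p_membrane"]:
            # membrane: bright rim plus faint out-of-focus lumen haze
            rim = inside & ~vac.contains(rr, cc, scale=1.0 - p["rim_width"] / max(vac.semi_axes))
            density = rim.astype(float) + p.get("lumen_haze", 0.0) * (inside & ~rim)
        else:
            density = inside.astype(float)
    elif class_label in ("endosome", "Golgi", "peroxisome"):
        lo, hi = p["n_puncta"]
        n = int(rng.integers(lo, hi + 1))
        interior = _erode(cell & ~nuc.contains(rr, cc, scale=1.1), 3)
        if not interior.any():
            interior = _erode(cell, 2)
        pts = _interior_points(rng, interior, n)
        density = _puncta(shape, pts, p["radius"])
    elif class_label == "mitochondria":
        lo, hi = p["n_branches"]
        interior = _erode(cell, 2)
        coords = np.argwhere(interior)
        canvas = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(lo, hi + 1))):
            r, c = coords[rng.integers(len(coords))].astype(float)
            ang = rng.uniform(0, 2 * math.pi)
            for _ in range(p["steps"]):
                ang += rng.normal(0, 0.5)
                r2, c2 = r + math.sin(ang), c + math.cos(ang)
                if 0 <= int(r2) < shape[0] and 0 <= int(c2) < shape[1] and interior[int(r2), int(c2)]:
                    r, c = r2, c2
                else:
                    ang += math.pi / 2
                canvas[int(r), int(c)] = True
        thick = max(1, int(round(p["thickness"])))
        canvas = ndi.binary_dilation(canvas, iterations=thick - 1) if thick > 1 else canvas
        density = (canvas & cell).astype(float)
    elif class_label == "cortical patches":
        lo, hi = p["n_puncta"]
        n = int(rng.integers(lo, hi + 1))
        band = _ring(cell, 3)
        pts = _interior_points(rng, band, n, min_sep=4.0)
        density = _puncta(shape, pts, p["radius"])
    elif class_label == "cell periphery":
        density = _ring(cell, int(round(p["ring_width"]))).astype(float)
    elif class_label == "bud":
        density = (geometry.bud.contains(rr, cc) & ~geometry.mother.contains(rr, cc, scale=0.92)).astype(float)
    elif class_label == "budneck":
        hw = p["half_width"]
        s = 1.0 + hw / max(geometry.mother.semi_axes)
        sb = 1.0 + hw / max(geometry.bud.semi_axes)
        neck = geometry.mother.contains(rr, cc, scale=s) & geometry.bud.contains(rr, cc, scale=sb)
        density = (neck & cell).astype(float)
    elif class_label == "budsite":
        band = _ring(cell, 3)
        pts = _interior_points(rng, band, 1)
        density = _puncta(shape, pts, p["radius"])
    elif class_label == "spindle pole":
        n_dots = p["n_dots"]
        if n_dots is None:
            n_dots = 2 if (geometry.budded and rng.random() < 0.5) else 1
        lo_s, hi_s = p["separation"] if isinstance(p["separation"], tuple) else (p["separation"], p["separation"])
        sep = rng.uniform(lo_s, hi_s)
        anchor = (nuc.center[0], nuc.center[1] + nuc.semi_axes[0])
        if n_dots == 1:
            pts = [anchor]
        else:
            ang = rng.uniform(0, 2 * math.pi)
            pts = [
                (anchor[0] - sep / 2 * math.sin(ang), anchor[1] - sep / 2 * math.cos(ang)),
                (anchor[0] + sep / 2 * math.sin(ang), anchor[1] + sep / 2 * math.cos(ang)),
            ]
        density = _puncta(shape, pts, p["radius"])

    if density.max() > 0:
        density = ndi.gaussian_filter(density, _PSF_SIGMA)
    return expression * density


# ---------------------------------------------------------------------------
# field generation


@dataclass
class PhantomSpec:
    """Recipe for one synthetic field of view."""

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 80
    class_mix: dict[str, float] = field(default_factory=lambda: {"cytoplasm": 1.0})
    budded_fraction: float = 0.35
    dead_fraction: float = 0.0
    ghost_fraction: float = 0.0
    gfp_gain: float = 1.0
    noise: tuple[float, float] = (2.0, 1.0)  # (gaussian_sd, poisson_scale)
    seed: int = 0
    rfp_level: float = 600.0
    expression_mean: float = 100.0
    expression_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        total = sum(self.class_mix.values())
        if self.class_mix:
            if any(v < 0 for v in self.class_mix.values()):
                raise ValueError("class_mix proportions must be >= 0")
            if abs(total - 1.0) > 1e-9:
                raise ValueError("class_mix proportions must sum to 1")
            unknown = set(self.class_mix) - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        elif self.n_cells > 0:
            raise ValueError("class_mix required when n_cells > 0")
        if not (0 <= self.budded_fraction <= 1):
            raise ValueError("budded_fraction must be in [0, 1]")
        if self.dead_fraction < 0 or self.ghost_fraction < 0:
            raise ValueError("artifact fractions must be >= 0")
        if self.dead_fraction + self.ghost_fraction >= 1:
            raise ValueError("dead_fraction + ghost_fraction must be < 1")

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["image_shape"] = list(self.image_shape)
        d["noise"] = list(self.noise)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruthCell:
    """Ground truth for one rendered object."""

    cell_id: int
    centroid: tuple[float, float]  # (x, y) = (col, row)
    geometry: CellGeometry | None
    true_classes: frozenset[str]
    cycle_stage: str
    is_dead: bool = False
    is_ghost: bool = False
    true_expression: float = 0.0


def _place_objects(
    rng: np.random.Generator,
    spec: PhantomSpec,
    radii: list[float],
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centers (disc approximation)."""
    h, w = spec.image_shape
    centers: list[tuple[float, float]] = []
    max_tries = 300 * max(1, len(radii))
    tries = 0
    for i, r in enumerate(radii):
        placed = False
        while tries < max_tries:
            tries += 1
            cr = rng.uniform(r + 1, h - r - 1) if h > 2 * r + 2 else h / 2
            cc = rng.uniform(r + 1, w - r - 1) if w > 2 * r + 2 else w / 2
            if all(
                math.hypot(cr - pr, cc - pc) > r + radii[j] + 2.0
                for j, (pr, pc) in enumerate(centers)
            ):
                centers.append((cr, cc))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"placed {i} of {len(radii)} objects in {spec.image_shape} "
                f"after {tries} attempts; reduce n_cells or enlarge the field"
            )
    return centers


def _render_dead(rng: np.random.Generator, shape: tuple[int, int], center) -> tuple[np.ndarray, CellGeometry]:
    """Shriveled, speckled red blob with no coherent structure."""
    a = rng.uniform(4.0, 7.0)
    b = a * rng.uniform(0.6, 1.0)
    geom = CellGeometry(Ellipse(center, (a, b), rng.uniform(0, math.pi)))
    mask = geom.mask(shape)
    texture = rng.uniform(0.2, 1.0, size=shape)
    img = np.where(mask, texture, 0.0)
    return ndi.gaussian_filter(img, 0.5), geom


def _render_ghost(rng: np.random.Generator, shape: tuple[int, int], center) -> tuple[np.ndarray, CellGeometry]:
    """Dim, smooth background blob (noise mistaken for signal)."""
    a = rng.uniform(6.0, 12.0)
    b = a * rng.uniform(0.6, 1.0)
    geom = CellGeometry(Ellipse(center, (a, b), rng.uniform(0, math.pi)))
    mask = geom.mask(shape).astype(float)
    return ndi.gaussian_filter(mask, 2.0), geom


def generate_micrograph(
    spec: PhantomSpec,
) -> tuple[Micrograph, Micrograph, list[GroundTruthCell]]:
    """Render one synthetic field: (RFP, GFP, ground truth).

    Live cells get a uniform cytoplasmic fill on the red channel and their
    class pattern on the green channel scaled by ``true_expression *
    gfp_gain``.  Dead cells are bright speckled red blobs; ghosts are dim
    red blobs with no green signal.  Objects never overlap (rejection
    sampling); an unplaceable spec raises :class:`PlacementError` with
    diagnostics.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    rfp = np.zeros((h, w), dtype=np.float64)
    gfp = np.zeros((h, w), dtype=np.float64)
    truth: list[GroundTruthCell] = []

    kinds: list[str] = []
    for _ in range(spec.n_cells):
        u = rng.random()
        if u < spec.dead_fraction:
            kinds.append("dead")
        elif u < spec.dead_fraction + spec.ghost_fraction:
            kinds.append("ghost")
        else:
            kinds.append("live")

    class_names = list(spec.class_mix) if spec.class_mix else []
    class_p = np.array([spec.class_mix[c] for c in class_names]) if class_names else None

    geoms: list[CellGeometry | None] = []
    labels: list[str | None] = []
    radii: list[float] = []
    for kind in kinds:
        if kind == "live":
            label = class_names[rng.choice(len(class_names), p=class_p)]
            budded = rng.random() < spec.budded_fraction or label in BUDDED_ONLY_CLASSES
            geom = sample_geometry(rng, budded)
            geoms.append(geom)
            labels.append(label)
            radii.append(geom.radius_bound())
        else:
            geoms.append(None)
            labels.append(None)
            radii.append(13.0)

    centers = _place_objects(rng, spec, radii)

    sigma = math.log(1 + spec.expression_cv**2) ** 0.5
    for i, (kind, center) in enumerate(zip(kinds, centers)):
        cell_id = i + 1
        if kind == "live":
            geom = geoms[i].shifted(*center)
            expr = spec.expression_mean * rng.lognormal(-sigma**2 / 2, sigma)
            pattern_seed = int(rng.integers(0, 2**31 - 1))
            gfp += render_pattern(labels[i], geom, expr * spec.gfp_gain, pattern_seed, shape=(h, w))
            rfp += ndi.gaussian_filter(geom.mask((h, w)).astype(float), 0.8) * spec.rfp_level
            truth.append(
                GroundTruthCell(
                    cell_id=cell_id,
                    centroid=(geom.center[1], geom.center[0]),
                    geometry=geom,
                    true_classes=frozenset({labels[i]}),
                    cycle_stage=geom.cycle_stage,
                    true_expression=expr,
                )
            )
        elif kind == "dead":
            img, geom = _render_dead(rng, (h, w), center)
            rfp += img * spec.rfp_level * 1.2
            truth.append(
                GroundTruthCell(
                    cell_id=cell_id,
                    centroid=(center[1], center[0]),
                    geometry=geom,
                    true_classes=frozenset(),
                    cycle_stage=UNBUDDED,
                    is_dead=True,
                )
            )
        else:
            img, geom = _render_ghost(rng, (h, w), center)
            rfp += img * spec.rfp_level * 0.30
            truth.append(
                GroundTruthCell(
                    cell_id=cell_id,
                    centroid=(center[1], center[0]),
                    geometry=geom,
                    true_classes=frozenset(),
                    cycle_stage=UNBUDDED,
                    is_ghost=True,
                )
            )

    gauss_sd, poisson_scale = spec.noise
    if poisson_scale > 0:
        rfp = rng.poisson(rfp * poisson_scale) / poisson_scale
        gfp = rng.poisson(gfp * poisson_scale) / poisson_scale
    if gauss_sd > 0:
        rfp = rfp + rng.normal(0, gauss_sd, size=rfp.shape)
        gfp = gfp + rng.normal(0, gauss_sd, size=gfp.shape)
    rfp = np.clip(rfp, 0, 4095)
    gfp = np.clip(gfp, 0, 4095)

    return (
        Micrograph(rfp, RFP),
        Micrograph(gfp, GFP),
        truth,
    )


# ---------------------------------------------------------------------------
# single-cell training crops


@dataclass
class TrainingCrop:
    """One labeled single-cell crop: both channels, mask, and truth."""

    label: str
    gfp: np.ndarray
    rfp: np.ndarray
    mask: np.ndarray
    cycle_stage: str
    is_positive: bool
    true_expression: float = 0.0


#: Labels accepted by :func:`render_crop` beyond the 16 classes.
SPECIAL_LABELS = ("dead", "ghost")


def render_crop(
    label: str,
    rng: np.random.Generator,
    *,
    stage: str | None = None,
    params: dict | None = None,
    noise: tuple[float, float] = (2.0, 1.0),
    rfp_level: float = 600.0,
    expression_mean: float = 100.0,
    expression_cv: float = 0.3,
) -> TrainingCrop:
    """Render one single-cell crop of ``label`` (a class, "dead" or "ghost").

    ``stage`` forces the cycle stage ("unbudded" or "budded"); classes
    that exist only on budded cells are always budded.
    """
    if label in SPECIAL_LABELS:
        shape = (40, 40)
        if label == "dead":
            img, geom = _render_dead(rng, shape, (20.0, 20.0))
            rfp = img * rfp_level * 1.2
        else:
            img, geom = _render_ghost(rng, shape, (20.0, 20.0))
            rfp = img * rfp_level * 0.30
        gfp = np.zeros(shape)
        mask = geom.mask(shape)
        crop = TrainingCrop(label, gfp, rfp, mask, UNBUDDED, True)
    else:
        if label not in CLASSES:
            raise ValueError(f"unknown crop label {label!r}")
        if stage == "budded" or label in BUDDED_ONLY_CLASSES:
            budded = True
        elif stage == UNBUDDED:
            budded = False
        elif stage in (SMALL_BUDDED, LARGE_BUDDED):
            budded = True
        else:
            budded = rng.random() < 0.35
        while True:
            geom = sample_geometry(rng, budded)
            if stage not in (SMALL_BUDDED, LARGE_BUDDED) or geom.cycle_stage == stage:
                break
        r = geom.radius_bound()
        size = int(math.ceil(2 * r + 10))
        geom = geom.shifted(size / 2 - geom.center[0], size / 2 - geom.center[1])
        shape = (size, size)
        sigma = math.log(1 + expression_cv**2) ** 0.5
        expr = expression_mean * rng.lognormal(-sigma**2 / 2, sigma)
        pattern_seed = int(rng.integers(0, 2**31 - 1))
        gfp = render_pattern(label, geom, expr, pattern_seed, shape=shape, params=params)
        mask = geom.mask(shape)
        rfp = ndi.gaussian_filter(mask.astype(float), 0.8) * rfp_level
        crop = TrainingCrop(label, gfp, rfp, mask, geom.cycle_stage, True, expr)

    gauss_sd, poisson_scale = noise
    for name in ("gfp", "rfp"):
        img = getattr(crop, name)
        if poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * poisson_scale) / poisson_scale
        if gauss_sd > 0:
            img = img + rng.normal(0, gauss_sd, size=img.shape)
        setattr(crop, name, np.clip(img, 0, 4095))
    return crop


def generate_training_set(
    class_label: str,
    n_pos: int,
    negative_mix: dict[str, float],
    n_neg: int,
    seed: int,
    *,
    pos_stage: str | None = None,
    pos_params: dict | None = None,
    noise: tuple[float, float] = (2.0, 1.0),
) -> list[TrainingCrop]:
    """Labeled single-cell crops: ``n_pos`` positives of ``class_label``
    plus ``n_neg`` negatives drawn from ``negative_mix`` (a mapping
    label -> proportion).  Mirrors the handpicked positive/negative
    training-object construction of the real screens.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if not negative_mix:
        raise ValueError("negative_mix must not be empty")
    total = sum(negative_mix.values())
    if total <= 0:
        raise ValueError("negative_mix proportions must sum to > 0")

    rng = np.random.default_rng(seed)
    crops: list[TrainingCrop] = []
    for _ in range(n_pos):
        crops.append(
            render_crop(class_label, rng, stage=pos_stage, params=pos_params, noise=noise)
        )
    neg_labels = list(negative_mix)
    p = np.array([negative_mix[k] for k in neg_labels], dtype=float) / total
    draws = rng.choice(len(neg_labels), size=n_neg, p=p)
    for d in draws:
        crop = render_crop(neg_labels[d], rng, noise=noise)
        crop.is_positive = False
        crops.append(crop)
    return crops


# ---------------------------------------------------------------------------
# file output


def write_phantom(
    out_dir: str | Path,
    spec: PhantomSpec,
    basename: str = "field",
) -> dict[str, Path]:
    """Generate a field and write TIFF pair, truth TSV, and spec JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rfp, gfp, truth = generate_micrograph(spec)
    paths = {
        "rfp": out / f"{basename}_rfp.tif",
        "gfp": out / f"{basename}_gfp.tif",
        "truth": out / f"{basename}_truth.tsv",
        "spec": out / f"{basename}_spec.json",
    }
    tifffile.imwrite(paths["rfp"], np.round(rfp.pixels).astype(np.uint16))
    tifffile.imwrite(paths["gfp"], np.round(gfp.pixels).astype(np.uint16))
    with open(paths["truth"], "w") as fh:
        fh.write("cell_id\tx\ty\tclasses\tcycle_stage\tis_dead\texpression\n")
        for t in truth:
            classes = ";".join(sorted(t.true_classes)) if t.true_classes else (
                "ghost" if t.is_ghost else ""
            )
            fh.write(
                f"{t.cell_id}\t{t.centroid[0]:.2f}\t{t.centroid[1]:.2f}\t"
                f"{classes}\t{t.cycle_stage}\t{int(t.is_dead)}\t{t.true_expression:.4f}\n"
            )
    paths["spec"].write_text(spec.to_json())
    return paths
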