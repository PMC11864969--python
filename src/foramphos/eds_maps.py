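"""Cryo-SEM–EDS elemental-map processing.

EDS maps of cryo-fractured foraminifera are dominated by a
position-dependent bremsstrahlung background, so raw count maps of minor
elements correlate with the total counts-per-second (CPS) map rather
than with true elemental enrichments. Under the assumption that the
background spectral shape is the same at every position, the per-pixel
intensity-to-noise ratio

    R(m,n) = I_i(m,n) / B_i(m,n) = S_i/B_i + 1
           = I_i(m,n) / (CPS(m,n) − Σ_i I_i(m,n))

suppresses that background: the denominator — total counts minus all
characteristic-peak counts — is the out-of-peak background, used as the
proxy for the background under element i's own peak. Pixels whose
denominator falls below a small ε are masked rather than clipped.

The rest of the treatment mirrors the original workflow: a one-pixel
(3×3) median filter to smooth enriched ultrastructures, a fixed
16-colour look-up table applied without modifying the underlying grey
values, manual similarity registration (scale + rotation + translation,
no warping) against the calcium map, and alpha-blended overlays on the
secondary-electron image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage import transform as sktransform

from .biovolume import ValidationError

DEFAULT_EPSILON = 1.0  # counts


@dataclass
class ElementCountMaps:
    """Co-registered per-element count maps plus the total-CPS map.

    Pixels where CPS < Σ_i I_i violate the count bookkeeping and are
    recorded in ``inconsistent`` (they will be masked downstream, never
    silently clipped).
    """

    counts: dict[str, np.ndarray]
    cps: np.ndarray

    def __post_init__(self) -> None:
        self.cps = np.asarray(self.cps, dtype=float)
        self.counts = {k: np.asarray(v, dtype=float) for k, v in self.counts.items()}
        if not self.counts:
            raise ValidationError("need at least one element map")
        for name, arr in self.counts.items():
            if arr.shape != self.cps.shape:
                raise ValidationError(
                    f"map {name!r} shape {arr.shape} != CPS shape {self.cps.shape}"
                )
            if (arr < 0).any():
                raise ValidationError(f"negative counts in map {name!r}")
        if (self.cps < 0).any():
            raise ValidationError("negative CPS values")

    @property
    def elements(self) -> list[str]:
        return list(self.counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cps.shape

    def total_characteristic(self) -> np.ndarray:
        return np.sum(list(self.counts.values()), axis=0)

    @property
    def inconsistent(self) -> np.ndarray:
        return self.cps < self.total_characteristic() - 1e-9


@dataclass
class RatioMap:
    """A per-pixel intensity-to-noise ratio map with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True = valid
    element: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")


def ratio_map(
    maps: ElementCountMaps,
    element: str,
    epsilon: float = DEFAULT_EPSILON,
    denominator: str = "all",
) -> RatioMap:
    """Intensity-to-noise ratio map for one element.

    ``denominator="all"`` subtracts every listed element's counts from
    CPS (the default reading of the bookkeeping); ``"exclude_target"``
    subtracts all elements except the target, for stacks where the
    target's own peak is not meant to be removed from the background
    estimate. Pixels with denominator < ``epsilon``, or with CPS below
    the summed characteristic counts, are masked.
    """
    if element not in maps.counts:
        raise KeyError(f"element {element!r} not in stack {maps.elements}")
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    if denominator not in ("all", "exclude_target"):
        raise ValidationError("denominator must be 'all' or 'exclude_target'")
    total = maps.total_characteristic()
    if denominator == "exclude_target":
        total = total - maps.counts[element]
    denom = maps.cps - total
    mask = (denom >= epsilon) & ~maps.inconsistent
    values = np.zeros_like(denom)
    np.divide(maps.counts[element], denom, out=values, where=mask)
    return RatioMap(values=values, mask=mask, element=element)


def median_filter(rmap: RatioMap, radius: int = 1) -> RatioMap:
    """Mask-aware median filter with a (2r+1)² window.

    Each valid pixel becomes the median of the *valid* pixels in its
    window; the window is clipped at the image borders (no padding
    values enter the median) and masked pixels never contribute. The
    mask itself is preserved.
    """
    if radius < 1:
        raise ValidationError("radius must be ≥ 1")
    w = 2 * radius + 1
    padded = np.full(
        (rmap.values.shape[0] + 2 * radius, rmap.values.shape[1] + 2 * radius),
        np.nan,
    )
    padded[radius:-radius, radius:-radius] = np.where(rmap.mask, rmap.values, np.nan)
    windows = sliding_window_view(padded, (w, w))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(windows, axis=(-2, -1))
    out = np.where(rmap.mask, med, rmap.values)
    out = np.where(np.isnan(out), rmap.values, out)
    return RatioMap(values=out, mask=rmap.mask.copy(), element=rmap.element)


# Fixed 16-entry palette (dark blue → red → white ramp, Fiji-style
# "16 colors"). Any fixed palette satisfies the rendering contract.
LUT16 = np.array(
    [
        (0, 0, 0), (1, 1, 171), (1, 1, 224), (0, 110, 255),
        (1, 171, 254), (1, 224, 254), (1, 254, 1), (190, 255, 0),
        (255, 255, 0), (255, 224, 0), (255, 141, 0), (250, 94, 0),
        (245, 0, 0), (245, 0, 172), (222, 180, 222), (255, 255, 255),
    ],
    dtype=np.uint8,
)


def lut_quantize(
    rmap: RatioMap,
    n_colours: int = 16,
    vmin: float | None = None,
    vmax: float | None = None,
    palette: np.ndarray = LUT16,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear binning of the valid range into ``n_colours`` classes.

    Returns ``(classes, rgba)``: integer class indices (masked pixels
    −1) and an RGBA uint8 rendering (masked pixels transparent). The
    underlying grey values are not modified — this is a rendering, the
    RatioMap stays as is. Classes are assigned by linear bins over
    [vmin, vmax] (defaults: min/max of valid pixels); a constant map
    collapses to class 0. Re-quantizing class indices is idempotent.
    """
    if not rmap.mask.any():
        raise ValidationError("all pixels masked; nothing to render")
    if len(palette) < n_colours:
        raise ValidationError("palette smaller than n_colours")
    valid = rmap.values[rmap.mask]
    lo = float(valid.min()) if vmin is None else vmin
    hi = float(valid.max()) if vmax is None else vmax
    if hi <= lo:
        classes = np.zeros_like(rmap.values, dtype=int)
    else:
        scaled = (rmap.values - lo) / (hi - lo) * n_colours
        classes = np.clip(np.floor(scaled), 0, n_colours - 1).astype(int)
    classes = np.where(rmap.mask, classes, -1)
    rgba = np.zeros(rmap.values.shape + (4,), dtype=np.uint8)
    rgba[rmap.mask, :3] = palette[classes[rmap.mask]]
    rgba[rmap.mask, 3] = 255
    return classes, rgba


@dataclass(frozen=True)
class SimilarityTransform:
    """Scale + rotation + translation, 4 degrees of freedom, no shear."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]  # (x, y) pixels
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be positive")

    def matrix(self) -> np.ndarray:
        t = sktransform.SimilarityTransform(
            scale=self.scale,
            rotation=np.deg2rad(self.rotation_deg),
            translation=self.translation,
        )
        return t.params


def register_similarity(points_moving: np.ndarray, points_fixed: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform from ≥2 control-point pairs.

    Points are (x, y) pixel coordinates, rows paired. The estimate is
    the closed-form least-squares (Umeyama) solution; the residual RMS
    over the control points is reported so a bad manual registration is
    visible.
    """
    src = np.asarray(points_moving, dtype=float)
    dst = np.asarray(points_fixed, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValidationError("need matching (n, 2) point arrays")
    if src.shape[0] < 2:
        raise ValidationError("need at least 2 control-point pairs")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValidationError("coincident control points: geometry is degenerate")
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        t = sktransform.SimilarityTransform.from_estimate(src, dst)
        if not t:
            raise ValidationError("similarity estimation failed (degenerate geometry)")
    else:  # skimage < 0.26
        t = sktransform.SimilarityTransform()
        if not t.estimate(src, dst):
            raise ValidationError("similarity estimation failed (degenerate geometry)")
    mapped = t(src)
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return SimilarityTransform(
        scale=float(t.scale),
        rotation_deg=float(np.rad2deg(t.rotation)),
        translation=(float(t.translation[0]), float(t.translation[1])),
        residual_rms=rms,
    )


def apply_transform(
    moving: np.ndarray,
    tform: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample ``moving`` onto the fixed grid under the transform."""
    t = sktransform.SimilarityTransform(matrix=tform.matrix())
    return sktransform.warp(
        np.asarray(moving, dtype=float),
        inverse_map=t.inverse,
        output_shape=output_shape,
        preserve_range=True,
        order=1,
    )


def overlay(base: np.ndarray, rendered: np.ndarray, alpha: float) -> np.ndarray:
    """Alpha-blend a rendered (RGBA) element map onto a greyscale image.

    Masked (transparent) pixels show the base only. Returns float RGB in
    the base image's intensity range.
    """
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must lie in [0, 1]")
    base = np.asarray(base, dtype=float)
    if rendered.shape[:2] != base.shape[:2]:
        raise ValidationError("base and overlay shapes differ — register first")
    base_rgb = np.stack([base] * 3, axis=-1) if base.ndim == 2 else base[..., :3]
    over_rgb = rendered[..., :3].astype(float)
    if rendered.dtype == np.uint8:
        over_rgb = over_rgb / 255.0 * (base_rgb.max() if base_rgb.max() > 0 else 1.0)
    opaque = rendered[..., 3] > 0 if rendered.shape[-1] == 4 else np.ones(base.shape[:2], bool)
    a = np.where(opaque, alpha, 0.0)[..., None]
    return (1 - a) * base_rgb + a * over_rgb


def estimate_contrast(
    maps: ElementCountMaps,
    element: str,
    inside: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    denominator: str = "all",
) -> float:
    """Signal-to-background contrast k of a region from count totals.

    With a fixed background spectral shape, the expected ratio R is
    constant within a homogeneous region, so the region estimate uses
    totals — R̂ = Σ I_i / Σ (CPS − Σ_i I_i) over the region's valid
    pixels — which keeps the Poisson error of the quotient small. The
    contrast of the ``inside`` region against the rest of the image is

        k̂ = R̂_inside / R̂_outside − 1,

    exactly the injected S_i/B_i for a noiseless phantom, independent of
    the (unknown) peak/continuum split.
    """
    inside = np.asarray(inside, dtype=bool)
    if inside.shape != maps.shape:
        raise ValidationError("region mask shape differs from maps")
    total = maps.total_characteristic()
    if denominator == "exclude_target":
        total = total - maps.counts[element]
    denom = maps.cps - total
    valid = (denom >= epsilon) & ~maps.inconsistent
    def _ratio(region: np.ndarray) -> float:
        sel = region & valid
        if not sel.any() or denom[sel].sum() <= 0:
            raise ValidationError("region has no valid pixels")
        return float(maps.counts[element][sel].sum() / denom[sel].sum())

    return _ratio(inside) / _ratio(~inside) - 1.0


# --- IO helpers -----------------------------------------------------------

def load_stack(paths: dict[str, str], cps_path: str) -> ElementCountMaps:
    """Read per-element maps and the CPS map (TIFF/PNG or delimited text)."""
    return ElementCountMaps(
        counts={el: _read_map(p) for el, p in paths.items()},
        cps=_read_map(cps_path),
    )


def _read_map(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    if path.endswith(".png"):
        from imageio import v3 as iio

        return np.asarray(iio.imread(path), dtype=float)
    return np.loadtxt(path, delimiter=None)


def save_ratio_map(rmap: RatioMap, path) -> None:
    """Write R as 32-bit TIFF; masked pixels stored as NaN."""
    import tifffile

    out = np.where(rmap.mask, rmap.values, np.nan).astype(np.float32)
    tifffile.imwrite(str(path), out)
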