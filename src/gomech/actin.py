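"""Nematic order analysis of actin fluorescence images.

The image is tiled into overlapping square blocks; each block's dominant
filament orientation (the *director*, axial, in [0, pi)) is estimated from
the principal axis of its 2D power spectrum.  The nematic order parameter
of a block,

    q = 2 (cos^2(theta) - 1/2) = cos(2 theta),

averaged over the director-angle differences ``theta`` between the block
and its surrounding blocks, quantifies local alignment: 1 for parallel
directors, 0 in expectation for random ones.  The module also provides
intensity masking, mean F-actin intensity, and two-channel live/dead
viability counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure, morphology

from gomech.errors import EmptyMaskError, InvalidParameterError


@dataclass
class Mask:
    """Boolean foreground mask with small components removed."""

    values: np.ndarray
    threshold: float
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class OrientationField:
    """Block-grid director angles (radians, [0, pi)) and coherence ([0, 1]).

    ``theta`` is nan where a block is unset (insufficient mask coverage or
    zero spectral anisotropy); ``set_mask`` marks set blocks.
    """

    theta: np.ndarray
    coherence: np.ndarray
    block_centers_y: np.ndarray
    block_centers_x: np.ndarray
    window: int
    overlap: float
    set_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.set_mask is None:
            self.set_mask = ~np.isnan(self.theta)

    @property
    def shape(self):
        return self.theta.shape


@dataclass
class QMap:
    """Order-parameter map over the block grid; nan where unset."""

    q: np.ndarray
    set_mask: np.ndarray
    neighborhood_radius: int


def make_intensity_mask(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_px: int = 0,
) -> Mask:
    """Threshold an image into a foreground mask.

    ``method`` is ``"otsu"`` (automatic) or ``"fixed"`` (requires
    ``threshold``).  Connected components smaller than ``min_area_px``
    are removed.  An empty result raises :class:`EmptyMaskError`.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("mask requires a single-channel image")
    if method == "otsu":
        thr = float(filters.threshold_otsu(img))
    elif method == "fixed":
        if threshold is None:
            raise InvalidParameterError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")
    mask = img > thr
    if min_area_px > 0:
        # remove components with area < min_area_px (max_size is inclusive)
        mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        raise EmptyMaskError("intensity mask is empty")
    return Mask(values=mask, threshold=thr, method=method)


def _block_director(block: np.ndarray):
    """Director angle and coherence of one block from its power spectrum.

    The block is mean-subtracted, Hann-tapered, and its centred power
    spectrum (DC bin removed, radially windowed to the usable annulus) is
    summarised by second moments over frequency coordinates.  The director
    is the axis orthogonal to the spectral major axis; coherence is the
    normalised eigenvalue anisotropy of the moment tensor.
    """
    n = block.shape[0]
    b = block - block.mean()
    hann = np.hanning(n)
    b = b * hann[:, None] * hann[None, :]
    power = np.abs(np.fft.fftshift(np.fft.fft2(b))) ** 2
    c = n // 2
    # frequency coordinates: u along columns (x), v along rows (y)
    v, u = np.mgrid[0:n, 0:n]
    u = u - c
    v = v - c
    r2 = u * u + v * v
    annulus = (r2 > 0) & (r2 <= (n // 2) ** 2)
    w = np.where(annulus, power, 0.0)
    total = w.sum()
    if total <= 0:
        return np.nan, 0.0
    muu = (w * u * u).sum() / total
    mvv = (w * v * v).sum() / total
    muv = (w * u * v).sum() / total
    # principal axis of the spectral moment tensor
    tr = muu + mvv
    diff = muu - mvv
    lam1 = 0.5 * (tr + np.hypot(diff, 2 * muv))
    lam2 = 0.5 * (tr - np.hypot(diff, 2 * muv))
    coherence = 0.0 if tr == 0 else (lam1 - lam2) / tr
    if coherence <= 1e-12:
        return np.nan, 0.0
    # spectral major axis angle in (u, v); rows index y downward, but the
    # convention cancels in angle *differences* and is fixed here so that a
    # horizontal filament (intensity varying along y only) maps to theta=0.
    phi = 0.5 * np.arctan2(2 * muv, diff)
    theta = (phi + np.pi / 2.0) % np.pi
    return float(theta), float(coherence)


def local_orientation(
    image: np.ndarray,
    window: int = 32,
    overlap: float = 0.5,
    mask: Mask | np.ndarray | None = None,
) -> OrientationField:
    """Blockwise director estimation over a regular overlapping grid.

    Blocks are ``window`` x ``window`` px, stepped by
    ``window * (1 - overlap)``.  Blocks with less than 50% of their pixels
    inside ``mask`` (when given) are left unset.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("orientation requires a single-channel image")
    if window < 16 or (window & (window - 1)) != 0:
        raise InvalidParameterError("window must be a power of two >= 16")
    if not 0.0 <= overlap <= 0.9:
        raise InvalidParameterError("overlap must lie in [0, 0.9]")
    h, w = img.shape
    if window > min(h, w):
        raise InvalidParameterError("window larger than image")
    m = None
    if mask is not None:
        m = mask.values if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
        if m.shape != img.shape:
            raise InvalidParameterError("mask shape differs from image")
    step = max(1, int(round(window * (1.0 - overlap))))
    ys = np.arange(0, h - window + 1, step)
    xs = np.arange(0, w - window + 1, step)
    theta = np.full((ys.size, xs.size), np.nan)
    coher = np.zeros((ys.size, xs.size))
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            if m is not None:
                cover = m[y0 : y0 + window, x0 : x0 + window].mean()
                if cover < 0.5:
                    continue
            theta[i, j], coher[i, j] = _block_director(
                img[y0 : y0 + window, x0 : x0 + window]
            )
    return OrientationField(
        theta=theta,
        coherence=coher,
        block_centers_y=ys + window / 2.0,
        block_centers_x=xs + window / 2.0,
        window=window,
        overlap=overlap,
    )


def order_parameter_map(field: OrientationField, radius: int = 1) -> QMap:
    """Nematic order parameter per block from neighbour director differences.

    For each set block i, ``q_i`` is the mean of ``cos(2 (theta_i -
    theta_j))`` over set blocks j within Chebyshev ``radius`` (the block
    itself excluded).  Blocks without any set neighbour are unset.
    """
    if radius < 1:
        raise InvalidParameterError("neighborhood radius must be >= 1")
    ny, nx = field.shape
    if ny * nx < (2 * radius + 1) ** 2:
        raise InvalidParameterError(
            f"field needs at least {(2 * radius + 1) ** 2} blocks"
        )
    theta, is_set = field.theta, field.set_mask
    q = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            if not is_set[i, j]:
                continue
            vals = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < ny and 0 <= b < nx and is_set[a, b]:
                        # axial difference folded into [0, pi/2]
                        d = abs(theta[i, j] - theta[a, b]) % np.pi
                        d = min(d, np.pi - d)
                        vals.append(np.cos(2.0 * d))
            if vals:
                q[i, j] = float(np.mean(vals))
    return QMap(q=q, set_mask=~np.isnan(q), neighborhood_radius=radius)


def mean_order_parameter(qmap: QMap) -> float:
    """Unweighted mean <q> over set blocks."""
    if not qmap.set_mask.any():
        raise InvalidParameterError("order-parameter map has no set blocks")
    return float(np.nanmean(qmap.q))


def mean_intensity(image: np.ndarray, mask: Mask | np.ndarray) -> float:
    """Arithmetic mean grey value over masked pixels."""
    img = np.asarray(image, dtype=float)
    m = mask.values if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise InvalidParameterError("mask shape differs from image")
    if not m.any():
        raise EmptyMaskError("mask is empty")
    return float(img[m].mean())


def count_cells(
    image: np.ndarray,
    threshold_method: str = "otsu",
    min_area_px: int = 0,
) -> int:
    """Number of connected foreground components in one channel."""
    img = np.asarray(image, dtype=float)
    if img.min() == img.max():  # blank channel: nothing to threshold
        return 0
    try:
        mask = make_intensity_mask(
            image, method=threshold_method, min_area_px=min_area_px
        )
    except EmptyMaskError:
        return 0
    return int(measure.label(mask.values).max())


def viability_from_channels(
    green_image: np.ndarray,
    red_image: np.ndarray,
    threshold_method: str = "otsu",
    min_area_px: int = 0,
) -> float:
    """Live/dead viability: percent of green (viable) cells among all cells.

    Each channel is masked and its connected components counted;
    ``viability = 100 * n_green / (n_green + n_red)``.
    """
    green = np.asarray(green_image)
    red = np.asarray(red_image)
    if green.shape != red.shape:
        raise InvalidParameterError("channel images differ in shape")
    n_green = count_cells(green, threshold_method, min_area_px)
    n_red = count_cells(red, threshold_method, min_area_px)
    if n_green + n_red == 0:
        raise InvalidParameterError("no cells detected in either channel")
    return 100.0 * n_green / (n_green + n_red)
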