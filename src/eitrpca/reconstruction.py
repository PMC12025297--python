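"""GREIT-style time-difference image reconstruction.

A linear reconstruction matrix maps a 192-length difference-voltage vector
(frame minus reference frame) to a 32 x 32 pixel image.  The matrix is
trained in the GREIT manner: small conductivity-decrease targets are placed
on a grid inside the homogeneous phantom, their (linearised) difference
voltages are computed with the FEM sensitivity matrix, and the
reconstruction matrix is the regularised least-squares map from those
voltages to "desired" images — narrow Gaussian blobs at the target
positions.  Training against conductivity *decreases* with positive desired
blobs fixes the clinical polarity: inspiration (falling lung conductivity)
reconstructs as positive pixels.

Image orientation: ventral at the top row, subject's right at the left
column (the standard clinical EIT display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .datamodel import VoltageMatrix, sum_waveform
from .forward import build_fem, measurement_jacobian
from .mesh import PhantomSpec

__all__ = [
    "ReconstructionModel",
    "EITImage",
    "ImageSeries",
    "build_reconstructor",
    "reconstruct_series",
    "reconstruct_frame",
    "feit_image",
    "pick_reference_frame",
]

IMAGE_SIDE = 32


@dataclass(frozen=True)
class EITImage:
    """One 32 x 32 reconstructed difference image (ventral = top row)."""

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        msk = np.asarray(self.mask, dtype=bool)
        if px.shape != (IMAGE_SIDE, IMAGE_SIDE) or msk.shape != px.shape:
            raise ValueError("images are 32 x 32")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixels")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "mask", msk)


@dataclass(frozen=True)
class ImageSeries:
    images: np.ndarray          # (n_frames, 32, 32)
    mask: np.ndarray
    reference_frame: int        # 1-based

    def __len__(self) -> int:
        return self.images.shape[0]

    def frame(self, t: int) -> EITImage:
        """1-based frame access."""
        return EITImage(pixels=self.images[t - 1], mask=self.mask)


@dataclass(frozen=True)
class ReconstructionModel:
    matrix: np.ndarray          # (1024, 192)
    pixel_mask: np.ndarray      # (32, 32) bool
    pixel_x: np.ndarray
    pixel_y: np.ndarray

    def apply(self, dv: np.ndarray) -> np.ndarray:
        """Reconstruct one difference vector into a 32 x 32 image."""
        return (self.matrix @ dv).reshape(IMAGE_SIDE, IMAGE_SIDE)


def _pixel_grid(phantom: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel centre coordinates and the in-body mask for the 32 x 32 grid.

    Row index grows dorsally (row 0 ventral = max y); column index grows
    toward the subject's left (+x).
    """
    bx, by = phantom.boundary[:, 0], phantom.boundary[:, 1]
    xmin, xmax = bx.min(), bx.max()
    ymin, ymax = by.min(), by.max()
    xs = xmin + (np.arange(IMAGE_SIDE) + 0.5) * (xmax - xmin) / IMAGE_SIDE
    ys = ymax - (np.arange(IMAGE_SIDE) + 0.5) * (ymax - ymin) / IMAGE_SIDE
    px, py = np.meshgrid(xs, ys)           # (row, col)
    from matplotlib.path import Path as _MplPath  # local import: optional dep

    mask = _MplPath(phantom.boundary).contains_points(
        np.column_stack([px.ravel(), py.ravel()])
    ).reshape(IMAGE_SIDE, IMAGE_SIDE)
    return px, py, mask


def _pixel_mask_fallback(phantom: PhantomSpec, px, py) -> np.ndarray:
    """Winding-free point-in-polygon via ray casting (no matplotlib)."""
    poly = phantom.boundary
    x, y = px.ravel(), py.ravel()
    inside = np.zeros(x.size, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cond = (y1 > y) != (y2 > y)
        xs = x1 + (y - y1) * (x2 - x1) / (y2 - y1 + 1e-300)
        inside ^= cond & (x < xs)
    return inside.reshape(px.shape)


def build_reconstructor(
    phantom: PhantomSpec,
    target_radius: float = 0.05,
    target_spacing: float = 0.09,
    psf_sigma: float = 0.08,
    regularization: float = 3e-2,
    target_amplitude: float = -0.1,
) -> ReconstructionModel:
    """Train the linear reconstruction matrix on the homogeneous phantom.

    Parameters (all relative to the domain radius) follow common GREIT
    practice: target radius 5%, desired Gaussian point-spread ~8%, a uniform
    target grid, and Tikhonov regularisation standing in for the noise-figure
    weighting.  All are configurable.

    Returns a model whose rows corresponding to out-of-body pixels are zero,
    so masked pixels reconstruct to exactly 0.
    """
    fem = build_fem(phantom)
    sigma0 = np.full(phantom.n_elements, phantom.background_conductivity)
    jac = measurement_jacobian(fem, sigma0)      # (192, n_elem)

    centroids = phantom.element_centroids()
    bx, by = phantom.boundary[:, 0], phantom.boundary[:, 1]
    scale = max(bx.max() - bx.min(), by.max() - by.min()) / 2.0

    # uniform target grid strictly inside the body
    px, py, mask = _pixel_grid_cached(phantom)
    xs = np.arange(bx.min(), bx.max(), target_spacing * scale)
    ys = np.arange(by.min(), by.max(), target_spacing * scale)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # keep targets where a small disc fits inside the boundary: use the
    # nearest-boundary distance
    d2b = np.min(
        np.hypot(pts[:, 0][:, None] - bx[None, :], pts[:, 1][:, None] - by[None, :]),
        axis=1,
    )
    pts = pts[d2b > 2.5 * target_radius * scale]

    ys_list, imgs_list = [], []
    r_t = target_radius * scale
    for cx, cy in pts:
        sel = np.hypot(centroids[:, 0] - cx, centroids[:, 1] - cy) <= r_t
        if not np.any(sel):
            continue
        dsigma = np.zeros(phantom.n_elements)
        dsigma[sel] = target_amplitude
        ys_list.append(jac @ dsigma)
        blob = np.exp(-((px - cx) ** 2 + (py - cy) ** 2) / (2 * (psf_sigma * scale) ** 2))
        blob = blob * mask
        blob /= blob.sum()
        imgs_list.append(blob.ravel())
    y = np.column_stack(ys_list)            # (192, K)
    x = np.column_stack(imgs_list)          # (1024, K)

    yyt = y @ y.T
    reg = regularization**2 * np.trace(yyt) / yyt.shape[0]
    rmat = x @ y.T @ np.linalg.inv(yyt + reg * np.eye(yyt.shape[0]))
    rmat[~mask.ravel(), :] = 0.0
    return ReconstructionModel(matrix=rmat, pixel_mask=mask, pixel_x=px, pixel_y=py)


_GRID_CACHE: dict[tuple, tuple] = {}


def _pixel_grid_cached(phantom: PhantomSpec):
    key = (phantom.style, phantom.n_elements, phantom.boundary.tobytes())
    if key not in _GRID_CACHE:
        try:
            _GRID_CACHE[key] = _pixel_grid(phantom)
        except ImportError:
            px_, py_ = _pixel_grid_coords(phantom)
            _GRID_CACHE[key] = (px_, py_, _pixel_mask_fallback(phantom, px_, py_))
    return _GRID_CACHE[key]


def _pixel_grid_coords(phantom: PhantomSpec):
    bx, by = phantom.boundary[:, 0], phantom.boundary[:, 1]
    xs = bx.min() + (np.arange(IMAGE_SIDE) + 0.5) * (bx.max() - bx.min()) / IMAGE_SIDE
    ys = by.max() - (np.arange(IMAGE_SIDE) + 0.5) * (by.max() - by.min()) / IMAGE_SIDE
    return np.meshgrid(xs, ys)


def reconstruct_frame(
    model: ReconstructionModel, v: VoltageMatrix, frame: int, reference_frame: int
) -> EITImage:
    """Reconstruct a single 1-based frame against a 1-based reference."""
    dv = v.data[:, frame - 1] - v.data[:, reference_frame - 1]
    return EITImage(pixels=model.apply(dv), mask=model.pixel_mask)


def reconstruct_series(
    model: ReconstructionModel, v: VoltageMatrix, reference_frame: int
) -> ImageSeries:
    """Reconstruct every frame against the reference (both 1-based)."""
    if not 1 <= reference_frame <= v.n_frames:
        raise ValueError("reference frame outside the recording")
    dv = v.data - v.data[:, [reference_frame - 1]]
    imgs = (model.matrix @ dv).T.reshape(-1, IMAGE_SIDE, IMAGE_SIDE)
    return ImageSeries(images=imgs, mask=model.pixel_mask,
                       reference_frame=reference_frame)


def feit_image(series: ImageSeries, sample_sd: bool = False) -> EITImage:
    """Functional EIT image: per-pixel standard deviation over time.

    Ventilated regions pulse with breathing and light up; static regions
    stay dark.  Population SD by default (``ddof=0``)."""
    if len(series) < 2:
        raise ValueError("fEIT needs at least 2 frames")
    sd = series.images.std(axis=0, ddof=1 if sample_sd else 0)
    return EITImage(pixels=sd * series.mask, mask=series.mask)


def pick_reference_frame(v: VoltageMatrix, near_frame: int) -> int:
    """Find the end-expiration frame (1-based) closest to ``near_frame``.

    End-expiration — maximum lung conductivity — is a local *minimum* of the
    all-channel voltage sum.  Ties break to the earlier frame.
    """
    w = sum_waveform(v)
    # local minima, with plateau handling
    minima, _ = scipy.signal.find_peaks(-w)
    if minima.size == 0:
        raise ValueError("no breathing cycle found in the recording")
    idx = minima + 1   # to 1-based
    best = idx[np.argmin(np.abs(idx - near_frame) + 1e-9 * (idx > near_frame))]
    return int(best)
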