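"""Image-quality metrics and clinical ventilation indices.

Two image metrics compare a processed image with a reference:

* ``image_correlation`` — Pearson correlation over all 1024 pixels;
* ``image_error`` — sqrt of the summed squared pixel error divided by the
  summed absolute reference pixel values (a scale-free error ratio).

Four clinical indices summarise a ventilation (fEIT) image:

* CoV, centre of ventilation: amplitude-weighted mean position along the
  ventral-dorsal axis, in percent of thoracic depth (0% = ventral edge);
* GI, global inhomogeneity: summed absolute deviation from the median
  pixel, normalised by the pixel sum;
* VtoD and RtoL: ventral/dorsal and right/left ratios of summed amplitudes.

Image convention: row 0 is ventral, column 0 is the subject's right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .reconstruction import EITImage, IMAGE_SIDE

__all__ = [
    "IndexReport",
    "image_correlation",
    "image_error",
    "center_of_ventilation",
    "global_inhomogeneity",
    "region_ratios",
    "index_report",
    "index_errors",
    "compare_groups",
]


@dataclass(frozen=True)
class IndexReport:
    """The four clinical indices, optionally with the two image metrics and
    per-index absolute errors against a reference report."""

    cov: float
    gi: float
    vtod: float
    rtol: float
    img_corr: float | None = None
    img_err: float | None = None
    deltas: dict | None = None

    def as_dict(self) -> dict:
        d = {"cov": self.cov, "gi": self.gi, "vtod": self.vtod, "rtol": self.rtol}
        if self.img_corr is not None:
            d["img_corr"] = self.img_corr
        if self.img_err is not None:
            d["img_err"] = self.img_err
        if self.deltas is not None:
            d["deltas"] = dict(self.deltas)
        return d


def _pixels(img: EITImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, EITImage) else np.asarray(img, dtype=float)


def image_correlation(a: EITImage | np.ndarray, b: EITImage | np.ndarray) -> float:
    """Pearson correlation between two images over all pixels."""
    x = _pixels(a).ravel()
    y = _pixels(b).ravel()
    if x.shape != y.shape:
        raise ValueError("images must have the same shape")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a zero-variance image")
    return float((xc * yc).sum() / denom)


def image_error(test: EITImage | np.ndarray, ref: EITImage | np.ndarray) -> float:
    """Root summed squared error over the summed absolute reference."""
    t = _pixels(test).ravel()
    r = _pixels(ref).ravel()
    if t.shape != r.shape:
        raise ValueError("images must have the same shape")
    denom = np.abs(r).sum()
    if denom == 0:
        raise ValueError("image error undefined for an all-zero reference")
    return float(np.sqrt(((t - r) ** 2).sum()) / denom)


def center_of_ventilation(img: EITImage | np.ndarray) -> float:
    """Amplitude-weighted ventral-dorsal position, percent of depth.

    Row distances are normalised by (32 - 1) so a uniform image scores 50%
    and all mass in the ventral-most row scores 0%.
    """
    px = _pixels(img)
    total = px.sum()
    if total <= 0:
        raise ValueError("CoV undefined for a non-positive image sum")
    li = np.arange(px.shape[0], dtype=float)[:, None] / (px.shape[0] - 1)
    return float((li * px).sum() / total * 100.0)


def global_inhomogeneity(img: EITImage | np.ndarray, roi: np.ndarray | None = None) -> float:
    """Summed |pixel - median| over the pixel sum.

    The median and sums run over the in-body mask by default (all pixels for
    a bare array); pass ``roi`` to restrict to a lung region of interest as
    in the clinical variant.
    """
    px = _pixels(img)
    if roi is None:
        roi = img.mask if isinstance(img, EITImage) else np.ones_like(px, dtype=bool)
    vals = px[roi]
    total = vals.sum()
    if total <= 0:
        raise ValueError("GI undefined for a non-positive image sum")
    return float(np.abs(vals - np.median(vals)).sum() / total)


def region_ratios(img: EITImage | np.ndarray) -> tuple[float, float]:
    """(ventral/dorsal, right/left) ratios of summed pixel values.

    Ventral = rows 0-15, dorsal = rows 16-31; the subject's right is image
    columns 0-15.
    """
    px = _pixels(img)
    half = px.shape[0] // 2
    ventral, dorsal = px[:half].sum(), px[half:].sum()
    right, left = px[:, :half].sum(), px[:, half:].sum()
    if dorsal <= 0 or left <= 0:
        raise ValueError("region ratio undefined: zero dorsal or left sum")
    return float(ventral / dorsal), float(right / left)


def index_report(
    img: EITImage | np.ndarray, ref: EITImage | np.ndarray | None = None
) -> IndexReport:
    """All four clinical indices of ``img``; adds the two image metrics and
    per-index absolute errors when a reference image is given."""
    cov = center_of_ventilation(img)
    gi = global_inhomogeneity(img)
    vtod, rtol = region_ratios(img)
    rep = IndexReport(cov=cov, gi=gi, vtod=vtod, rtol=rtol)
    if ref is None:
        return rep
    ref_rep = index_report(ref)
    rep = IndexReport(
        cov=cov, gi=gi, vtod=vtod, rtol=rtol,
        img_corr=image_correlation(img, ref),
        img_err=image_error(img, ref),
    )
    return index_errors(rep, ref_rep)


def index_errors(test: IndexReport, ref: IndexReport) -> IndexReport:
    """Absolute per-index differences |test - ref|, attached as ``deltas``."""
    deltas = {
        "cov": abs(test.cov - ref.cov),
        "gi": abs(test.gi - ref.gi),
        "vtod": abs(test.vtod - ref.vtod),
        "rtol": abs(test.rtol - ref.rtol),
    }
    return IndexReport(
        cov=test.cov, gi=test.gi, vtod=test.vtod, rtol=test.rtol,
        img_corr=test.img_corr, img_err=test.img_err, deltas=deltas,
    )


def compare_groups(
    before, after, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided independent-samples t-test between two metric groups."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size < 2 or after.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = scipy.stats.ttest_ind(before, after, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
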