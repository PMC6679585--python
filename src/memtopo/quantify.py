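"""Static quantifications of membrane images.

Implements the membrane-profile workflow used to compare feature classes:
a band of configurable width is computationally straightened along a
membrane path, background is subtracted, and each annotated crossing
(single membrane "PM", filopodium "Filo", double-membrane furrow "Furrow")
is scored by the sum of its three brightest samples, normalized per embryo
to the median of the single-membrane crossings. Also provides two-channel
relative enrichment, ROI colocalization scoring, structure-count time
courses, and the anterior/posterior asymmetry index

    ASI = (A - P) / [2 (A + P)]            in [-0.5, 0.5]

from cortical means or from a straightened cross-section contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MembranePath",
    "ProfileTrace",
    "Crossing",
    "EnrichmentRecord",
    "extract_profile",
    "peak_metric",
    "enrichment_table",
    "summarize_enrichment",
    "relative_enrichment",
    "colocalization_fraction",
    "count_timecourse",
    "asi_cortical",
    "asi_cross_section",
]


class PathError(ValueError):
    """Membrane path invalid or outside the image."""


class DegenerateSignalError(ValueError):
    """No usable signal (e.g. zero membrane signal after subtraction)."""


@dataclass
class MembranePath:
    """Ordered path vertices in pixel units (0-based, pixel-center)."""

    vertices_px: np.ndarray  # (N, 2) as (x, y)
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices_px = np.asarray(self.vertices_px, dtype=float)
        if self.vertices_px.ndim != 2 or self.vertices_px.shape[0] < 2:
            raise PathError("path needs >= 2 vertices")

    def resample(self, step_px: float = 1.0) -> np.ndarray:
        """Unit-speed resampling of the path at `step_px` spacing."""
        v = self.vertices_px
        if self.closed and not np.allclose(v[0], v[-1]):
            v = np.vstack([v, v[0]])
        seg = np.hypot(*np.diff(v, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] <= 0:
            raise PathError("path has zero length")
        n = max(int(np.floor(arc[-1] / step_px)) + 1, 2)
        s = np.linspace(0.0, arc[-1], n)
        x = np.interp(s, arc, v[:, 0])
        y = np.interp(s, arc, v[:, 1])
        return np.column_stack([x, y])


@dataclass
class ProfileTrace:
    """Straightened band profile along a membrane path.

    ``raw`` is the band-averaged, background-subtracted intensity;
    ``normalized`` is raw divided by its mean (None when degenerate).
    """

    positions_um: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None
    band: np.ndarray  # (n_samples, band_width) straightened band
    degenerate: bool = False
    source: str = ""


def _band_coordinates(pts: np.ndarray, band_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates of a band of `band_width` 1-px-spaced lines
    normal to the path. Returns (rows, cols) arrays (n_samples, band_width)."""
    tang = np.gradient(pts, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(band_width, dtype=float) - (band_width - 1) / 2.0
    xs = pts[:, 0:1] + normal[:, 0:1] * offsets[None, :]
    ys = pts[:, 1:2] + normal[:, 1:2] * offsets[None, :]
    return ys, xs  # row, col


def extract_profile(image: np.ndarray, path: MembranePath,
                    band_width: int = 3, presmooth_sigma: float = 1.0,
                    chip_background: float = 0.0,
                    pixel_size_um: float = 0.155,
                    step_px: float = 1.0) -> ProfileTrace:
    """Straighten a band along a membrane path and return its profile.

    The image is Gaussian-smoothed (sigma = 1 px by default) to reduce
    noise, the path resampled at unit speed, and `band_width` bilinear
    samples taken along the local normal at each arclength step and
    averaged. The chip background is subtracted and the profile
    mean-normalized; an all-background profile is flagged degenerate
    instead of being normalized.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("extract_profile expects a single 2-D plane")
    pts = path.resample(step_px)
    rows, cols = _band_coordinates(pts, band_width)
    ny, nx = image.shape
    out = ((rows < -0.5) | (rows > ny - 0.5) | (cols < -0.5) | (cols > nx - 0.5))
    if np.any(out):
        i = int(np.argwhere(out.any(axis=1))[0][0])
        raise PathError(
            f"band sample exits the image near path point "
            f"({pts[i, 0]:.1f}, {pts[i, 1]:.1f}) px")
    sm = ndimage.gaussian_filter(image, presmooth_sigma) if presmooth_sigma > 0 else image
    band = ndimage.map_coordinates(sm, [rows, cols], order=1, mode="nearest")
    raw = band.mean(axis=1) - chip_background
    mean = raw.mean()
    degenerate = not np.isfinite(mean) or abs(mean) < 1e-12
    if degenerate:
        warnings.warn("profile is indistinguishable from background; "
                      "mean-normalization skipped", stacklevel=2)
    arclength = np.arange(len(raw)) * step_px * pixel_size_um
    return ProfileTrace(
        positions_um=arclength, raw=raw,
        normalized=None if degenerate else raw / mean,
        band=band, degenerate=degenerate)


def peak_metric(window: np.ndarray, cytoplasm_background: float = 0.0) -> float:
    """Sum of the three largest background-subtracted samples in a window.

    Samples need not be contiguous; negative background-subtracted values
    are clipped at zero before summing. Invariant to how ties are ordered.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 3:
        raise ValueError(f"crossing window needs >= 3 samples, got {w.size}")
    vals = np.clip(w - cytoplasm_background, 0.0, None)
    return float(np.sort(vals)[-3:].sum())


@dataclass
class Crossing:
    """Annotated membrane-feature crossing window on a profile."""

    label: str  # "PM" | "Filo" | "Furrow"
    center_px: float  # arclength position along the profile, px
    halfwidth_px: int = 5
    embryo_id: str = "embryo0"


@dataclass
class EnrichmentRecord:
    embryo_id: str
    label: str
    raw: float
    normalized: float | None = None


def enrichment_table(image: np.ndarray, path: MembranePath,
                     crossings: list[Crossing],
                     cytoplasm_background: float = 0.0,
                     chip_background: float = 0.0,
                     band_width: int = 3,
                     presmooth_sigma: float = 1.0,
                     pixel_size_um: float = 0.155) -> list[EnrichmentRecord]:
    """Score annotated crossings on one embryo/image by the top-3 metric.

    Each record's normalized value is its raw top-3 sum divided by the
    median raw value over the single-membrane ("PM") crossings of the same
    embryo, so PM median = 1 by construction.
    """
    if not any(c.label == "PM" for c in crossings):
        raise ValueError("at least one PM (single membrane) crossing is required")
    trace = extract_profile(image, path, band_width=band_width,
                            presmooth_sigma=presmooth_sigma,
                            chip_background=chip_background,
                            pixel_size_um=pixel_size_um)
    records: list[EnrichmentRecord] = []
    n = len(trace.raw)
    for c in crossings:
        lo = int(round(c.center_px - c.halfwidth_px))
        hi = int(round(c.center_px + c.halfwidth_px)) + 1
        if lo < 0 or hi > n:
            raise ValueError(
                f"crossing at {c.center_px} px (halfwidth {c.halfwidth_px}) "
                f"falls outside the profile of length {n}")
        raw = peak_metric(trace.raw[lo:hi], cytoplasm_background)
        records.append(EnrichmentRecord(c.embryo_id, c.label, raw))
    for emb in {r.embryo_id for r in records}:
        pm = [r.raw for r in records if r.embryo_id == emb and r.label == "PM"]
        med = float(np.median(pm))
        if med <= 0:
            raise DegenerateSignalError(
                f"embryo {emb}: PM median is zero; cannot normalize")
        for r in records:
            if r.embryo_id == emb:
                r.normalized = r.raw / med
    return records


def summarize_enrichment(records: list[EnrichmentRecord], n_boot: int = 10_000,
                         seed: int = 0) -> dict:
    """Per-class median of normalized values with 95% percentile-bootstrap CI."""
    rng = np.random.default_rng(seed)
    out: dict = {}
    for label in sorted({r.label for r in records}):
        vals = np.array([r.normalized for r in records if r.label == label])
        med = float(np.median(vals))
        if len(vals) > 1:
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boots = np.median(vals[idx], axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
        else:
            lo = hi = med
        out[label] = {"median": med, "ci95": (float(lo), float(hi)),
                      "n": int(len(vals))}
    return out


def relative_enrichment(records_ch1: list[EnrichmentRecord],
                        records_ch2: list[EnrichmentRecord],
                        label: str = "Filo") -> dict:
    """Ratio of median normalized enrichment between two channels.

    Channels must be quantified at the same crossings (same order). Also
    returns the mean +- s.d. of per-embryo mean crossing-wise ratios.
    """
    f1 = [r for r in records_ch1 if r.label == label]
    f2 = [r for r in records_ch2 if r.label == label]
    if not f1 or not f2:
        raise ValueError(f"no {label!r} crossings in one of the channels")
    if len(f1) != len(f2):
        raise ValueError("channels were not quantified at the same crossings")
    ratio = float(np.median([r.normalized for r in f1])
                  / np.median([r.normalized for r in f2]))
    per_embryo = []
    for emb in sorted({r.embryo_id for r in f1}):
        rs = [a.normalized / b.normalized for a, b in zip(f1, f2)
              if a.embryo_id == emb]
        if rs:
            per_embryo.append(float(np.mean(rs)))
    return {"ratio_of_medians": ratio,
            "per_embryo_mean": float(np.mean(per_embryo)),
            "per_embryo_sd": float(np.std(per_embryo, ddof=1)) if len(per_embryo) > 1 else 0.0,
            "n_embryos": len(per_embryo)}


def _roi_mask(shape: tuple[int, int], rois: list[tuple[float, float, float]]
              ) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for x, y, r in rois:
        mask |= (xx - x) ** 2 + (yy - y) ** 2 <= r ** 2
    return mask


def colocalization_fraction(ref_rois: list[tuple[float, float, float]],
                            test_image: np.ndarray, k: float = 3.0,
                            min_rois: int = 30) -> float:
    """Fraction of reference-channel structures labeled in the test channel.

    Each ROI is (x_px, y_px, radius_px), defined on well-separated
    structures in the reference channel. A structure scores positive when
    the test-channel maximum inside its ROI exceeds the local membrane
    background (median outside all ROIs) by k robust standard deviations
    (1.4826 x MAD) of that background. Fewer than `min_rois` ROIs triggers
    a warning (the protocol expects >= 30); zero ROIs is an error.
    """
    if len(ref_rois) == 0:
        raise ValueError("no ROIs supplied")
    if len(ref_rois) < min_rois:
        warnings.warn(
            f"only {len(ref_rois)} ROIs (< {min_rois}); fraction computed "
            "anyway but is poorly determined", stacklevel=2)
    img = np.asarray(test_image, dtype=float)
    inside = _roi_mask(img.shape, ref_rois)
    bg_vals = img[~inside]
    if bg_vals.size == 0:
        raise ValueError("ROIs cover the whole image; no background left")
    bg = float(np.median(bg_vals))
    sigma_rob = 1.4826 * float(np.median(np.abs(bg_vals - bg)))
    thr = bg + k * sigma_rob
    positives = 0
    for x, y, r in ref_rois:
        m = _roi_mask(img.shape, [(x, y, r)])
        if img[m].size and img[m].max() > thr:
            positives += 1
    return positives / len(ref_rois)


def count_timecourse(counts: np.ndarray) -> np.ndarray:
    """Per-frame structure counts normalized to the series peak."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty count series")
    peak = c.max()
    if peak <= 0:
        raise ValueError("all-zero count series cannot be peak-normalized")
    return c / peak


def asi_cortical(A: float, P: float) -> float:
    """Asymmetry index (A - P) / [2 (A + P)] of anterior/posterior means.

    0 is symmetric; +0.5 / -0.5 are maximal anterior / posterior polarity.
    """
    if A < 0 or P < 0:
        raise ValueError("mean intensities must be non-negative")
    if A + P == 0:
        raise ValueError("A + P must be positive")
    return (A - P) / (2.0 * (A + P))


def asi_cross_section(image: np.ndarray, contour: MembranePath,
                      cytoplasm_reference: np.ndarray,
                      band_width: int = 50,
                      inner_edge_px: int = 5,
                      presmooth_sigma: float = 1.0) -> float:
    """ASI from a straightened membrane band around a midplane cross-section.

    A `band_width`-px band following the closed embryo contour is
    straightened. ``cytoplasm_reference`` is the normalized cytoplasmic
    intensity profile *across* the band (cytoplasmic haze decaying from the
    inside of the embryo outward, e.g. measured on a structure-free
    stretch); at each arclength position it is scaled to match the band's
    cytoplasm-proximal edge and subtracted, isolating membrane signal.
    Anterior and posterior thirds of the circumference (the contour must
    start at the anterior pole) are then averaged and passed to
    :func:`asi_cortical`.
    """
    if not contour.closed:
        raise PathError("cross-section ASI requires a closed contour")
    trace = extract_profile(image, contour, band_width=band_width,
                            presmooth_sigma=presmooth_sigma)
    band = trace.band  # (n, band_width)
    n = band.shape[0]
    ref = np.asarray(cytoplasm_reference, dtype=float)
    if ref.ndim != 1:
        raise ValueError("cytoplasm_reference must be 1-D")
    if len(ref) != band_width:
        ref = np.interp(np.linspace(0, 1, band_width),
                        np.linspace(0, 1, len(ref)), ref)
    if ref.mean() <= 0:
        raise ValueError("cytoplasm reference must have positive mean")
    ref = ref / ref.mean()
    # decide which band edge faces the cytoplasm: the one nearer the centroid
    pts = contour.resample()
    centroid = pts.mean(axis=0)
    rows, cols = _band_coordinates(pts, band_width)
    d_first = np.hypot(cols[:, 0] - centroid[0], rows[:, 0] - centroid[1]).mean()
    d_last = np.hypot(cols[:, -1] - centroid[0], rows[:, -1] - centroid[1]).mean()
    inner_cols = (slice(None, inner_edge_px) if d_first < d_last
                  else slice(-inner_edge_px, None))
    ref_inner = ref[inner_cols].mean()
    if ref_inner <= 0:
        raise ValueError(
            "cytoplasm reference is zero at the cytoplasm-proximal edge")
    scale = band[:, inner_cols].mean(axis=1) / ref_inner  # per position
    membrane = (band - scale[:, None] * ref[None, :]).mean(axis=1)
    cyto_level = float(np.mean(scale) * ref.mean())
    if membrane.max() <= 0.05 * cyto_level:
        raise DegenerateSignalError(
            "no membrane signal above the scaled cytoplasm reference")
    membrane = np.clip(membrane, 0.0, None)
    sixth = n // 6
    anterior = np.concatenate([membrane[:sixth], membrane[-sixth:]])
    mid = n // 2
    posterior = membrane[mid - sixth: mid + sixth]
    return asi_cortical(float(anterior.mean()), float(posterior.mean()))
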