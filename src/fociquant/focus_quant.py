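"""Per-nucleus gamma-H2AX focus enumeration from two-channel images.

The pipeline mirrors the manual workflow it automates: a preset enhancement
chain applied identically to every image (auto-contrast, auto-levels,
desaturate, invert), nucleus segmentation from the DAPI channel with QC
exclusion of deformed or fragmented nuclei, multi-scale Laplacian-of-Gaussian
spot detection on the Cy3 channel alone, and enumeration restricted to foci
that fall inside a QC-passing DAPI nucleus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops


class SingleCellQCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Preset enhancement chain


@dataclass(frozen=True)
class PresetConfig:
    """Histogram clip fractions for the two auto-stretch steps.

    The 0.001 default is the classical 0.1% clip of desktop auto-contrast
    tools.  ``apply_order`` is fixed; it exists so a pipeline log can state
    the chain explicitly.
    """

    clip_fraction_low: float = 0.001
    clip_fraction_high: float = 0.001
    apply_order: tuple[str, ...] = ("auto_contrast", "auto_levels",
                                    "desaturate", "invert")

    def validate(self) -> None:
        for name in ("clip_fraction_low", "clip_fraction_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.05:
                raise ValueError(f"{name} must be in [0, 0.05]")
        if self.apply_order != ("auto_contrast", "auto_levels",
                                "desaturate", "invert"):
            raise ValueError("apply_order is fixed: auto_contrast, auto_levels, "
                             "desaturate, invert")


def _dtype_vmax(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0  # float rasters are treated as [0, 1]


def _stretch(band: np.ndarray, lo: float, hi: float, vmax: float) -> np.ndarray:
    if hi <= lo:
        return band.copy()
    return np.clip((band - lo) * (vmax / (hi - lo)), 0.0, vmax)


def preset_enhance(channel: np.ndarray, cfg: PresetConfig | None = None
                   ) -> np.ndarray:
    """Apply the fixed enhancement chain to a single- or three-band raster.

    auto-contrast stretches all bands with one common scale taken from the
    luminance histogram; auto-levels repeats the stretch per band; desaturate
    replaces each band by the mid-channel gray 0.5*(max+min) across bands
    (identity for single-band input); invert maps v to vmax - v.  Output
    dtype and range match the input bit depth.  A constant image has no
    dynamic range: it is returned unchanged except for inversion, with a
    warning.
    """
    cfg = cfg or PresetConfig()
    cfg.validate()
    if channel.ndim not in (2, 3):
        raise ValueError("expected a 2D band or (H, W, bands) raster")
    if not np.all(np.isfinite(channel)):
        raise ValueError("intensities must be finite")
    dtype = channel.dtype
    vmax = _dtype_vmax(channel)
    x = channel.astype(float)
    bands = x[..., None] if x.ndim == 2 else x

    luminance = bands.mean(axis=-1)
    lo = float(np.quantile(luminance, cfg.clip_fraction_low))
    hi = float(np.quantile(luminance, 1.0 - cfg.clip_fraction_high))
    if hi <= lo:
        warnings.warn("constant image: auto stretch skipped, invert applied",
                      stacklevel=2)
        out = vmax - bands
    else:
        out = _stretch(bands, lo, hi, vmax)  # auto_contrast: common scale
        for b in range(out.shape[-1]):      # auto_levels: per-band scale
            blo = float(np.quantile(out[..., b], cfg.clip_fraction_low))
            bhi = float(np.quantile(out[..., b], 1.0 - cfg.clip_fraction_high))
            if bhi > blo:
                out[..., b] = _stretch(out[..., b], blo, bhi, vmax)
        gray = 0.5 * (out.max(axis=-1) + out.min(axis=-1))  # desaturate
        out = np.repeat(gray[..., None], out.shape[-1], axis=-1)
        out = vmax - out                    # invert
    out = out[..., 0] if channel.ndim == 2 else out
    if np.issubdtype(dtype, np.integer):
        return np.clip(np.round(out), 0, vmax).astype(dtype)
    return out.astype(dtype)


# ---------------------------------------------------------------------------
# Nucleus segmentation and QC


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation + QC thresholds.

    QC accepts nuclei with solidity >= ``solidity_min``, area within
    [median/area_factor, median*area_factor] of the image's median nucleus
    area, and no contact with the image border — the shape proxy for the
    exclusion of deformed/fragmented (presumably apoptotic) nuclei.
    """

    smooth_sigma_px: float = 2.0
    solidity_min: float = 0.85
    area_factor: float = 3.0


@dataclass
class NucleusRecord:
    label: int
    area_px: int
    solidity: float
    touches_border: bool
    qc_pass: bool
    coords: np.ndarray          # (n_px, 2) int array of (row, col)
    image_shape: tuple[int, int]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


def segment_nuclei(dapi: np.ndarray, cfg: SegmentationConfig | None = None
                   ) -> list[NucleusRecord]:
    """Smooth, Otsu-threshold, fill holes, label (8-connectivity), QC."""
    cfg = cfg or SegmentationConfig()
    x = dapi.astype(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("DAPI raster must be finite")
    if np.ptp(x) == 0:
        return []
    sm = ndimage.gaussian_filter(x, cfg.smooth_sigma_px)
    binary = sm > threshold_otsu(sm)
    if not binary.any():
        return []
    binary = ndimage.binary_fill_holes(binary)
    labels = cc_label(binary, connectivity=2)
    props = regionprops(labels)
    if not props:
        return []
    # area-weighted median component area: the reference "typical nucleus"
    # size must not be dragged down by small apoptotic fragments, which can
    # outnumber intact nuclei even though they carry little total area
    areas = np.sort([p.area for p in props])
    cum = np.cumsum(areas)
    med_area = float(areas[np.searchsorted(cum, cum[-1] / 2.0)])
    h, w = labels.shape
    records = []
    for p in props:
        minr, minc, maxr, maxc = p.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        area_ok = med_area / cfg.area_factor <= p.area <= med_area * cfg.area_factor
        qc = (not touches) and area_ok and p.solidity >= cfg.solidity_min
        records.append(NucleusRecord(
            label=int(p.label), area_px=int(p.area),
            solidity=float(p.solidity), touches_border=bool(touches),
            qc_pass=bool(qc), coords=np.asarray(p.coords),
            image_shape=(h, w)))
    return records


# ---------------------------------------------------------------------------
# Focus detection


@dataclass(frozen=True)
class FociDetectionConfig:
    """Multi-scale LoG detector settings.

    Scales are log-spaced in [sigma_min_px, sigma_max_px]; foci can be very
    small or quite large, so detection runs over a scale range rather than a
    single width.  ``detection_threshold`` is relative to the global maximum
    of the scale-normalized response.
    """

    sigma_min_px: float = 1.0
    sigma_max_px: float = 2.5
    n_scales: int = 5
    detection_threshold: float = 0.10
    min_separation_px: float = 3.0

    def validate(self) -> None:
        if self.sigma_min_px <= 0 or self.sigma_max_px <= 0:
            raise ValueError("sigmas must be positive")
        if self.sigma_min_px >= self.sigma_max_px:
            raise ValueError("sigma_min_px must be < sigma_max_px")
        if self.n_scales < 1:
            raise ValueError("n_scales must be positive")
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValueError("detection_threshold must be in (0, 1)")
        if self.min_separation_px <= 0:
            raise ValueError("min_separation_px must be positive")


@dataclass(frozen=True)
class FocusDetection:
    row: float
    col: float
    sigma_px: float
    response: float


def detect_foci(cy3: np.ndarray, cfg: FociDetectionConfig | None = None
                ) -> list[FocusDetection]:
    """Scale-normalized LoG blob detection for bright spots.

    A candidate is a local maximum (over space and scale) of the
    sigma^2-normalized negative Laplacian-of-Gaussian response exceeding
    ``detection_threshold`` times the global response maximum.  Candidates
    closer than ``min_separation_px`` are merged, keeping the stronger.
    """
    cfg = cfg or FociDetectionConfig()
    cfg.validate()
    x = cy3.astype(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("Cy3 raster must be finite")
    if np.ptp(x) == 0:
        return []
    sigmas = np.geomspace(cfg.sigma_min_px, cfg.sigma_max_px, cfg.n_scales)
    stack = np.stack([-(s ** 2) * ndimage.gaussian_laplace(x, s)
                      for s in sigmas])
    gmax = float(stack.max())
    # numerical floor: the separable filter leaves O(eps * intensity) error
    # on flat regions, which must never clear the relative threshold
    floor = 1e-8 * float(np.abs(x).max() + 1.0)
    if gmax <= floor:
        return []
    thr = max(cfg.detection_threshold * gmax, floor)
    local_max = ndimage.maximum_filter(stack, size=(3, 3, 3), mode="nearest")
    cand = np.argwhere((stack >= local_max) & (stack > thr))
    if cand.size == 0:
        return []
    responses = stack[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.argsort(-responses)
    kept: list[FocusDetection] = []
    min_sep2 = cfg.min_separation_px ** 2
    for i in order:
        s, r, c = cand[i]
        if any((r - k.row) ** 2 + (c - k.col) ** 2 < min_sep2 for k in kept):
            continue
        kept.append(FocusDetection(row=float(r), col=float(c),
                                   sigma_px=float(sigmas[s]),
                                   response=float(responses[i])))
    return kept


# ---------------------------------------------------------------------------
# Per-nucleus enumeration


@dataclass(frozen=True)
class CellFociRecord:
    image_id: str
    nucleus_label: int
    foci_count: int
    foci_xy: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.foci_count != len(self.foci_xy):
            raise ValueError("foci_count must equal len(foci_xy)")


def count_foci_per_nucleus(detections: list[FocusDetection],
                           nuclei: list[NucleusRecord],
                           image_id: str = "") -> list[CellFociRecord]:
    """Assign each detection to the QC-passing nucleus whose mask contains it.

    Detections outside every QC-passing mask are discarded.  One record is
    emitted per QC-passing nucleus, including zero-count nuclei.  Ties on a
    shared pixel are impossible for disjoint labels; with duplicate labels
    the lower label wins by construction of the lookup.
    """
    passing = [n for n in nuclei if n.qc_pass]
    records = {n.label: [] for n in sorted(passing, key=lambda n: n.label)}
    if passing:
        shape = passing[0].image_shape
        label_map = np.zeros(shape, dtype=int)
        for n in sorted(passing, key=lambda n: n.label, reverse=True):
            label_map[n.coords[:, 0], n.coords[:, 1]] = n.label
        for d in detections:
            r, c = int(round(d.row)), int(round(d.col))
            if 0 <= r < shape[0] and 0 <= c < shape[1]:
                lab = int(label_map[r, c])
                if lab:
                    records[lab].append((d.row, d.col))
    return [CellFociRecord(image_id=image_id, nucleus_label=lab,
                           foci_count=len(pts), foci_xy=tuple(sorted(pts)))
            for lab, pts in records.items()]


def quantify_image(img, preset_cfg: PresetConfig | None = None,
                   seg_cfg: SegmentationConfig | None = None,
                   foci_cfg: FociDetectionConfig | None = None,
                   image_id: str = "") -> list[CellFociRecord]:
    """Full pipeline on one two-channel image.

    The Cy3 channel is enhanced with the preset chain (which ends inverted,
    dark spots on light, the polarity used for visual counting) and then
    re-inverted so the blob detector sees bright spots; nuclei come from the
    raw DAPI channel.
    """
    enhanced = preset_enhance(img.cy3, preset_cfg)
    vmax = _dtype_vmax(enhanced)
    bright = vmax - enhanced.astype(float)
    detections = detect_foci(bright, foci_cfg)
    nuclei = segment_nuclei(img.dapi, seg_cfg)
    return count_foci_per_nucleus(detections, nuclei, image_id=image_id)


def patient_mean_foci(records: list[CellFociRecord]
                      ) -> tuple[float, float, int]:
    """Pool QC-passing cells across a patient's images: (mean, SEM, n_cells)."""
    if not records:
        raise SingleCellQCError("no QC-passing cells for this patient")
    counts = np.array([r.foci_count for r in records], dtype=float)
    n = counts.size
    sem = float(counts.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return float(counts.mean()), sem, int(n)


# ---------------------------------------------------------------------------
# Tabular output


def per_cell_table(records: list[CellFociRecord],
                   nuclei_by_image: dict[str, list[NucleusRecord]] | None = None
                   ) -> pd.DataFrame:
    nuc_info = {}
    if nuclei_by_image:
        for img_id, nucs in nuclei_by_image.items():
            for n in nucs:
                nuc_info[(img_id, n.label)] = n
    rows = []
    for r in records:
        n = nuc_info.get((r.image_id, r.nucleus_label))
        rows.append({
            "image_id": r.image_id, "nucleus_label": r.nucleus_label,
            "area_px": n.area_px if n else np.nan,
            "solidity": n.solidity if n else np.nan,
            "qc_pass": n.qc_pass if n else True,
            "foci_count": r.foci_count,
        })
    return pd.DataFrame(rows)


def per_patient_table(records_by_patient: dict[str, list[CellFociRecord]]
                      ) -> pd.DataFrame:
    rows = []
    for pid, recs in records_by_patient.items():
        mean, sem, n = patient_mean_foci(recs)
        rows.append({"patient_id": pid, "mean_foci_per_cell": mean,
                     "sem": sem, "n_cells": n})
    return pd.DataFrame(rows)
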