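"""Synthetic two-channel fluorescence micrographs with known focus ground truth.

Emulates cytospin slides of mononuclear cells imaged at high magnification:
a DAPI channel carrying the nuclei and a Cy3 channel carrying punctate
gamma-H2AX foci.  Every image comes with its generative ground truth
(nucleus geometry, deformation flags, planted focus coordinates) so that the
downstream counting pipeline can be validated against exact planted counts.

Conventions: rasters are (row, col), 0-based, pixel centers at integer
coordinates.  Images are written as 2-page TIFF (page 1 DAPI, page 2 Cy3)
with a JSON ground-truth sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage


class OvercrowdingError(RuntimeError):
    """Raised when non-overlapping nucleus placement cannot be satisfied."""


class ImageFormatError(ValueError):
    """Raised when a TIFF does not have the expected two-page layout."""


# DAPI nuclear brightness as a fraction of the dynamic range; the simulator
# keeps this fixed so segmentation difficulty is controlled by noise_sd alone.
_DAPI_LEVEL_FRACTION = 0.40


@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of one simulated field of view.

    ``stress_level`` is a cytocentrifugation-style damage knob: it adds to the
    Poisson focus rate, emulating the qualitative increase in DNA damage seen
    at higher spin speeds.  ``deformed_fraction`` controls how many nuclei are
    rendered fragmented/concave (the apoptotic-looking cells a QC filter must
    exclude).
    """

    image_width_px: int = 512
    image_height_px: int = 512
    n_nuclei: int = 30
    nucleus_radius_px: float = 18.0
    nucleus_radius_spread: float = 0.12  # relative SD of the radius, in [0, 1)
    focus_rate_lambda: float = 4.25
    focus_sigma_px: float = 1.5
    focus_amplitude: float = 15000.0
    deformed_fraction: float = 0.05
    stress_level: float = 0.0
    background_level: float = 800.0
    noise_sd: float = 200.0
    bit_depth: int = 16
    pixel_size_um: float = 0.065
    seed: int = 0

    def validate(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if not 0.0 <= self.nucleus_radius_spread < 1.0:
            raise ValueError("nucleus_radius_spread must be in [0, 1)")
        for name in ("focus_rate_lambda", "stress_level", "background_level",
                     "noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.focus_sigma_px <= 0 or self.focus_amplitude <= 0:
            raise ValueError("focus_sigma_px and focus_amplitude must be positive")
        if not 0.0 <= self.deformed_fraction <= 1.0:
            raise ValueError("deformed_fraction must be in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class TwoChannelImage:
    """A registered DAPI + Cy3 raster pair."""

    dapi: np.ndarray
    cy3: np.ndarray
    pixel_size_um: float
    bit_depth: int

    def __post_init__(self) -> None:
        if self.dapi.shape != self.cy3.shape:
            raise ValueError("dapi and cy3 must have identical dimensions")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class NucleusTruth:
    center_rc: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation_rad: float
    deformed: bool


@dataclass(frozen=True)
class FocusTruth:
    nucleus_index: int
    center_rc: tuple[float, float]


@dataclass(frozen=True)
class ImageGroundTruth:
    nuclei: tuple[NucleusTruth, ...]
    foci: tuple[FocusTruth, ...]

    def foci_counts(self) -> np.ndarray:
        """Planted focus count per nucleus (index-aligned with ``nuclei``)."""
        counts = np.zeros(len(self.nuclei), dtype=int)
        for f in self.foci:
            counts[f.nucleus_index] += 1
        return counts


def _in_ellipse(r: float, c: float, nuc: NucleusTruth, scale: float = 1.0) -> bool:
    dr = r - nuc.center_rc[0]
    dc = c - nuc.center_rc[1]
    ca, sa = math.cos(nuc.orientation_rad), math.sin(nuc.orientation_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = nuc.semi_axes[0] * scale, nuc.semi_axes[1] * scale
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi_axes: tuple[float, float], theta: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(theta), math.sin(theta)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _place_nuclei(params: ImageSimParams, rng: np.random.Generator
                  ) -> list[NucleusTruth]:
    """Rejection-sample non-overlapping ellipses with a small clearance.

    Centers stay far enough from the border that no nucleus touches the image
    edge; pairwise clearance of a few pixels keeps segmented masks disjoint
    after smoothing.
    """
    clearance = 5.0
    deformed_flags = rng.random(params.n_nuclei) < params.deformed_fraction
    nuclei: list[NucleusTruth] = []
    max_attempts = 200 * max(params.n_nuclei, 1)
    attempts = 0
    while len(nuclei) < params.n_nuclei:
        if attempts >= max_attempts:
            raise OvercrowdingError(
                f"could not place {params.n_nuclei} non-overlapping nuclei in a "
                f"{params.image_height_px}x{params.image_width_px} image after "
                f"{max_attempts} attempts")
        attempts += 1
        # radius spread truncated at 2 SD: no degenerate or giant nuclei
        z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
        radius = params.nucleus_radius_px * (1.0 + params.nucleus_radius_spread * z)
        elong = rng.uniform(1.0, 1.25)
        a, b = radius * elong, radius / elong
        margin = max(a, b) + 4.0
        if (params.image_height_px <= 2 * margin
                or params.image_width_px <= 2 * margin):
            raise OvercrowdingError(
                f"nucleus radius {radius:.1f}px does not fit in a "
                f"{params.image_height_px}x{params.image_width_px} image")
        r0 = rng.uniform(margin, params.image_height_px - margin)
        c0 = rng.uniform(margin, params.image_width_px - margin)
        rmax = max(a, b)
        ok = True
        for other in nuclei:
            omax = max(other.semi_axes)
            d = math.hypot(r0 - other.center_rc[0], c0 - other.center_rc[1])
            if d <= rmax + omax + clearance:
                ok = False
                break
        if ok:
            nuclei.append(NucleusTruth((r0, c0), (a, b),
                                       rng.uniform(0.0, math.pi),
                                       bool(deformed_flags[len(nuclei)])))
    return nuclei


def _plant_foci(nuclei: list[NucleusTruth], params: ImageSimParams,
                rng: np.random.Generator) -> list[FocusTruth]:
    """Plant Poisson-distributed foci uniformly inside each nucleus.

    Foci keep an edge margin inside the ellipse (spots are chromatin-bound,
    so they sit wholly within the nucleus) and a minimum mutual separation of
    3.5 focus widths: two Gaussian spots closer than that blur into a single
    peak, which no resolution-limited counter (human or algorithmic) can
    split, so the simulator plants discrete, individually resolvable foci.
    """
    rate = params.focus_rate_lambda + params.stress_level
    min_sep = 3.5 * params.focus_sigma_px
    edge_margin = 2.0 * params.focus_sigma_px
    foci: list[FocusTruth] = []
    for idx, nuc in enumerate(nuclei):
        k = int(rng.poisson(rate))
        if k == 0:
            continue
        a, b = nuc.semi_axes
        # keep sampled centers >= edge_margin inside the rim, but never
        # shrink a small nucleus below half its size
        shrink = max(0.5, min((a - edge_margin) / a, (b - edge_margin) / b))
        ca = math.cos(nuc.orientation_rad)
        sa = math.sin(nuc.orientation_rad)

        def candidates(m: int) -> np.ndarray:
            t = rng.uniform(0.0, 2 * math.pi, m)
            u = np.sqrt(rng.uniform(0.0, 1.0, m))
            x = a * shrink * u * np.cos(t)
            y = b * shrink * u * np.sin(t)
            return np.column_stack([nuc.center_rc[0] + x * ca - y * sa,
                                    nuc.center_rc[1] + x * sa + y * ca])

        # hard-core dart throwing with restarts keeps positions near-uniform;
        # for crowded nuclei a best-candidate (Mitchell) pass packs close to
        # the hexagonal limit before the separation is relaxed stepwise —
        # nuclei that genuinely cannot host k separated foci also carry
        # unresolvable foci in real images
        placed = np.empty((0, 2))
        done = False
        for relax in (1.0, 0.75, 0.5, 0.25, 0.0):
            sep = min_sep * relax
            for attempt in range(30):
                mitchell = attempt >= 15
                placed = candidates(1)
                for _ in range(k - 1):
                    cand = candidates(64)
                    d2min = ((cand[:, None, :] - placed[None, :, :]) ** 2
                             ).sum(-1).min(axis=1)
                    if mitchell:
                        pick = int(np.argmax(d2min))
                        if d2min[pick] < sep * sep:
                            break
                    else:
                        valid = np.flatnonzero(d2min >= sep * sep)
                        if valid.size == 0:
                            break
                        pick = int(valid[0])
                    placed = np.vstack([placed, cand[pick]])
                if placed.shape[0] == k:
                    done = True
                    break
            if done:
                break
        foci.extend(FocusTruth(idx, (float(r), float(c)))
                    for r, c in placed)
    return foci


def _render_nucleus(shape: tuple[int, int], nuc: NucleusTruth,
                    rng: np.random.Generator) -> np.ndarray:
    """Binary footprint of one nucleus; deformed ones are fragmented or concave."""
    if not nuc.deformed:
        return _ellipse_mask(shape, nuc.center_rc, nuc.semi_axes,
                             nuc.orientation_rad)
    if rng.random() < 0.5:
        # fragmented: 2-4 small disjoint pieces inside the parent footprint
        n_frag = int(rng.integers(2, 5))
        mask = np.zeros(shape, dtype=bool)
        a, b = nuc.semi_axes
        frag_r = max(2.5, min(a, b) / 3.5)
        centers: list[tuple[float, float]] = []
        for _ in range(n_frag):
            for _attempt in range(200):
                t = rng.uniform(0.0, 2 * math.pi)
                u = math.sqrt(rng.uniform(0.0, 1.0))
                r = nuc.center_rc[0] + 0.7 * a * u * math.cos(t)
                c = nuc.center_rc[1] + 0.7 * b * u * math.sin(t)
                # clearance large enough that segmentation smoothing cannot
                # bridge fragments back into one convex-looking blob
                if all(math.hypot(r - pr, c - pc) > 2 * frag_r + 8
                       for pr, pc in centers):
                    centers.append((r, c))
                    break
        for (r, c) in centers:
            mask |= _ellipse_mask(shape, (r, c), (frag_r, frag_r * 0.8),
                                  rng.uniform(0.0, math.pi))
        return mask
    # concave: thick horseshoe (annular arc) — hollow core plus a wide
    # opening; the band is thick enough that segmentation smoothing cannot
    # round it back to a convex blob, so solidity stays well below the QC cut
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - nuc.center_rc[0]
    dc = cc - nuc.center_rc[1]
    ca, sa = math.cos(nuc.orientation_rad), math.sin(nuc.orientation_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    rho2 = (u / nuc.semi_axes[0]) ** 2 + (v / nuc.semi_axes[1]) ** 2
    phi = rng.uniform(0.0, 2 * math.pi)
    ang_diff = np.abs((np.arctan2(dc, dr) - phi + math.pi)
                      % (2 * math.pi) - math.pi)
    return (rho2 <= 1.0) & (rho2 >= 0.45 ** 2) & (ang_diff > math.pi / 3)


def generate_image(params: ImageSimParams
                   ) -> tuple[TwoChannelImage, ImageGroundTruth]:
    """Render one simulated field of view plus its generative ground truth.

    DAPI: smooth filled nuclei over a flat background.  Cy3: isotropic
    Gaussian spots at the planted focus positions.  Gaussian read noise of SD
    ``noise_sd`` is added to both channels, then intensities are clipped to
    the bit range.  Bit-for-bit reproducible for a given parameter set.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.image_height_px, params.image_width_px)
    vmax = float(2 ** params.bit_depth - 1)

    nuclei = _place_nuclei(params, rng)
    foci = _plant_foci(nuclei, params, rng)

    footprint = np.zeros(shape, dtype=float)
    for nuc in nuclei:
        footprint[_render_nucleus(shape, nuc, rng)] = 1.0
    dapi = params.background_level + _DAPI_LEVEL_FRACTION * vmax * \
        ndimage.gaussian_filter(footprint, 1.0)

    cy3 = np.full(shape, params.background_level, dtype=float)
    sig = params.focus_sigma_px
    half = int(math.ceil(4 * sig))
    for f in foci:
        r0, c0 = f.center_rc
        ri, ci = int(round(r0)), int(round(c0))
        rlo, rhi = max(0, ri - half), min(shape[0], ri + half + 1)
        clo, chi = max(0, ci - half), min(shape[1], ci + half + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        cy3[rlo:rhi, clo:chi] += params.focus_amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig ** 2))

    if params.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, params.noise_sd, shape)
        cy3 = cy3 + rng.normal(0.0, params.noise_sd, shape)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    dapi = np.clip(np.round(dapi), 0, vmax).astype(dtype)
    cy3 = np.clip(np.round(cy3), 0, vmax).astype(dtype)

    img = TwoChannelImage(dapi=dapi, cy3=cy3,
                          pixel_size_um=params.pixel_size_um,
                          bit_depth=params.bit_depth)
    truth = ImageGroundTruth(nuclei=tuple(nuclei), foci=tuple(foci))
    return img, truth


# ---------------------------------------------------------------------------
# I/O: 2-page TIFF (DAPI, Cy3) + JSON ground-truth sidecar


def write_image(img: TwoChannelImage, path: str | Path) -> None:
    stack = np.stack([img.dapi, img.cy3])
    tifffile.imwrite(
        path, stack,
        description=json.dumps({"pixel_size_um": img.pixel_size_um,
                                "bit_depth": img.bit_depth,
                                "channels": ["DAPI", "Cy3"]}))


def read_image(path: str | Path) -> TwoChannelImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ImageFormatError(
            f"{path}: expected a 2-page TIFF (DAPI, Cy3), got shape {stack.shape}")
    meta = {}
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        pass
    bit_depth = int(meta.get("bit_depth", 8 if stack.dtype == np.uint8 else 16))
    return TwoChannelImage(dapi=stack[0], cy3=stack[1],
                           pixel_size_um=float(meta.get("pixel_size_um", 0.065)),
                           bit_depth=bit_depth)


def write_ground_truth(truth: ImageGroundTruth, path: str | Path) -> None:
    payload = {
        "nuclei": [dataclasses.asdict(n) for n in truth.nuclei],
        "foci": [dataclasses.asdict(f) for f in truth.foci],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> ImageGroundTruth:
    payload = json.loads(Path(path).read_text())
    nuclei = tuple(NucleusTruth(center_rc=tuple(n["center_rc"]),
                                semi_axes=tuple(n["semi_axes"]),
                                orientation_rad=n["orientation_rad"],
                                deformed=n["deformed"])
                   for n in payload["nuclei"])
    foci = tuple(FocusTruth(nucleus_index=f["nucleus_index"],
                            center_rc=tuple(f["center_rc"]))
                 for f in payload["foci"])
    return ImageGroundTruth(nuclei=nuclei, foci=foci)


def focus_in_nucleus(focus: FocusTruth, truth: ImageGroundTruth) -> bool:
    """True if a planted focus lies inside its parent nucleus ellipse."""
    return _in_ellipse(*focus.center_rc, truth.nuclei[focus.nucleus_index])
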