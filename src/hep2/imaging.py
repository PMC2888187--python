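"""Image data model, autofocus scoring, tile QC and exposure normalization.

A field of view pairs a DAPI chromatin channel (used for object detection,
focusing and mitosis identification) with a FITC autoantibody channel.
Focus is scored from grey-level co-occurrence: an in-focus image has many
strong grey-scale transitions between neighbouring pixels, so the contrast
moment of the unit-offset co-occurrence matrix is a sharpness measure that
collapses to zero on a constant image and decays under defocus blur.

Artifact screening divides the image into tiles of equal size and flags
tiles whose upper-percentile intensity is a robust outlier relative to the
other tiles (or which are saturated); exposure normalization then rescales
so the brightest non-artifact signal sits at a fixed reference level,
emulating adaptive exposure-time control in software.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelImage",
    "FieldOfView",
    "QCReport",
    "focus_score",
    "autofocus_select",
    "qc_tiles",
    "normalize_exposure",
    "read_channel",
    "read_manifest",
]

TILE_OK = "ok"
TILE_ARTIFACT = "artifact"
TILE_EMPTY = "empty"


@dataclass(frozen=True)
class ChannelImage:
    """Single-channel grey-scale image with acquisition metadata.

    ``pixels`` may be integer or float but must lie in [0, 2**bit_depth - 1].
    ``exposure_gain`` accumulates the multiplicative rescaling applied by
    :func:`normalize_exposure` (1.0 = as acquired).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    channel: str = "fitc"
    exposure_gain: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.channel not in ("dapi", "fitc"):
            raise ValueError("channel must be 'dapi' or 'fitc'")
        if self.exposure_gain <= 0:
            raise ValueError("exposure_gain must be positive")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError("pixel values outside [0, 2^bit_depth - 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FieldOfView:
    """One paired DAPI + FITC acquisition."""

    dapi: ChannelImage
    fitc: ChannelImage
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.dapi.shape != self.fitc.shape:
            raise ValueError("DAPI and FITC channels must share dimensions")


@dataclass(frozen=True)
class QCReport:
    """Tile-level quality flags and the derived artifact mask."""

    tile_grid: tuple[int, int]
    tile_flags: np.ndarray  # object array of flag strings, shape = tile_grid
    artifact_mask: np.ndarray  # bool, image shape
    usable: bool
    tile_bounds: tuple = field(default=(), repr=False)

    @property
    def artifact_fraction(self) -> float:
        return float((self.tile_flags == TILE_ARTIFACT).mean())


def _quantize(image: ChannelImage, levels: int) -> np.ndarray:
    """Map the full dtype range onto ``levels`` grey levels."""
    q = (image.pixels.astype(np.float64) * levels) / (image.max_value + 1)
    return np.clip(q.astype(np.int64), 0, levels - 1)


def focus_score(image: ChannelImage, levels: int = 64) -> float:
    """Co-occurrence contrast moment as a sharpness measure.

    Quantizes to ``levels`` grey levels, accumulates the symmetric
    co-occurrence matrix over the unit offsets (0,1) and (1,0), and
    returns sum p(i,j) * (i-j)^2.  Zero iff the image is constant.
    """
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    q = _quantize(image, levels)
    # Contrast moment needs only the distribution of level differences,
    # so accumulate (i-j)^2 directly over both unit offsets.
    dh = q[:, 1:] - q[:, :-1]
    dv = q[1:, :] - q[:-1, :]
    total = dh.size + dv.size
    return float((np.sum(dh.astype(np.int64) ** 2) + np.sum(dv.astype(np.int64) ** 2)) / total)


def autofocus_select(stack: list[ChannelImage], levels: int = 64) -> int:
    """Index of the sharpest image in a focal stack.

    Ties are broken toward the middle of the stack (then lower index),
    matching the expectation that the in-focus plane lies centrally.
    """
    if not stack:
        raise ValueError("empty focal stack")
    scores = np.array([focus_score(im, levels) for im in stack])
    best = np.flatnonzero(scores == scores.max())
    mid = (len(stack) - 1) / 2.0
    return int(min(best, key=lambda i: (abs(i - mid), i)))


def _tile_slices(shape: tuple[int, int], grid: tuple[int, int]):
    rows, cols = grid
    h, w = shape
    if rows > h or cols > w:
        raise ValueError("grid larger than image")
    redges = np.linspace(0, h, rows + 1).round().astype(int)
    cedges = np.linspace(0, w, cols + 1).round().astype(int)
    return [
        [(slice(redges[r], redges[r + 1]), slice(cedges[c], cedges[c + 1])) for c in range(cols)]
        for r in range(rows)
    ]


def qc_tiles(
    image: ChannelImage,
    grid: tuple[int, int] = (4, 4),
    mad_k: float = 5.0,
    saturation_frac: float = 0.01,
    empty_foreground_frac: float = 0.005,
    max_artifact_fraction: float = 0.25,
    mad_floor_frac: float = 0.25,
    saturation_level: float = 0.95,
) -> QCReport:
    """Flag tiles as ok / artifact / empty and derive an artifact mask.

    A tile is empty when its foreground fraction falls below
    ``empty_foreground_frac`` (foreground = above Otsu, floored at a
    robust background bound so pure noise never counts).  A tile is an
    artifact when more than ``saturation_frac`` of its pixels sit at or
    above ``saturation_level`` of the dtype range — the primary
    detector: real streaks and debris burn toward saturation — or when
    its 99th-percentile intensity is a robust outlier, exceeding the
    non-empty tiles' median 99th percentile by ``mad_k`` MADs (floored
    at ``mad_floor_frac`` of that median) *and* the whole image's 99.9th
    percentile.  The outlier guard terms keep legitimately uneven
    staining — sparse cells, discrete dot patterns, bright mitotic
    figures — below the artifact line.  All criteria are ratios of
    image statistics, hence invariant to global linear rescaling.  The
    field is unusable when more than ``max_artifact_fraction`` of tiles
    are artifacts.
    """
    px = image.pixels.astype(np.float64)
    tiles = _tile_slices(image.shape, grid)
    rows, cols = grid

    fg_mask = np.zeros(image.shape, bool)
    if np.ptp(px) > 0:
        # Otsu alone splits the noise band when true foreground is sparse
        # (e.g. dot patterns); a robust floor keeps background out.
        med_i = np.median(px)
        mad_i = np.median(np.abs(px - med_i))
        fg_mask = px > max(threshold_otsu(px), med_i + 5 * mad_i)

    p99 = np.array([[np.percentile(px[tiles[r][c]], 99) for c in range(cols)] for r in range(rows)])
    empty = np.array([
        [float(fg_mask[tiles[r][c]].mean()) < empty_foreground_frac for c in range(cols)]
        for r in range(rows)
    ])
    reference = p99[~empty] if (~empty).any() else p99.ravel()
    med = np.median(reference)
    mad = max(np.median(np.abs(reference - med)), mad_floor_frac * med)
    global_p999 = np.percentile(px, 99.9)

    flags = np.full((rows, cols), TILE_OK, dtype=object)
    artifact_mask = np.zeros(image.shape, bool)
    for r in range(rows):
        for c in range(cols):
            sl = tiles[r][c]
            saturated = float(np.mean(px[sl] >= saturation_level * image.max_value))
            outlier = p99[r, c] > med + mad_k * mad and p99[r, c] > global_p999
            if saturated > saturation_frac or outlier:
                flags[r, c] = TILE_ARTIFACT
                artifact_mask[sl] = True
            elif empty[r, c]:
                flags[r, c] = TILE_EMPTY

    usable = float((flags == TILE_ARTIFACT).mean()) <= max_artifact_fraction
    return QCReport(
        tile_grid=grid, tile_flags=flags, artifact_mask=artifact_mask,
        usable=usable, tile_bounds=tuple(tuple(row) for row in tiles),
    )


def normalize_exposure(
    image: ChannelImage,
    artifact_mask: np.ndarray | None = None,
    reference_frac: float = 0.9,
    percentile: float = 100.0,
) -> ChannelImage:
    """Rescale so the brightest clean signal hits a fixed reference level.

    The exposure controller this emulates keys on the highest image
    signal after exclusion of artifacts, so by default the *maximum*
    non-artifact pixel is mapped onto ``reference_frac`` of the dtype
    range (a lower ``percentile`` can be configured, at the price of
    clipping the peaks above it).  The multiplier is accumulated into
    ``exposure_gain``; values are kept as floats so that re-normalizing
    is an exact identity.
    """
    px = image.pixels.astype(np.float64)
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, bool)
        if artifact_mask.shape != image.shape:
            raise ValueError("artifact mask shape mismatch")
        clean = px[~artifact_mask]
        if clean.size == 0:
            raise ValueError("all pixels are masked as artifact")
    else:
        clean = px.ravel()
    ref = reference_frac * image.max_value
    p = float(np.percentile(clean, percentile))
    if p <= 0:
        raise ValueError("image has no signal to normalize")
    gain = ref / p
    scaled = np.minimum(px * gain, float(image.max_value))
    return replace(image, pixels=scaled, exposure_gain=image.exposure_gain * gain)


# ---------------------------------------------------------------------------
# File I/O

def read_channel(path, channel: str, bit_depth: int | None = None) -> ChannelImage:
    """Read a single-channel 8/16-bit TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    if px.ndim == 3:  # greyscale stored with a trailing singleton/colour axis
        px = px[..., 0]
    if bit_depth is None:
        bit_depth = 8 if px.dtype == np.uint8 else 16
    return ChannelImage(px, bit_depth=bit_depth, channel=channel)


def read_manifest(manifest_csv) -> list[FieldOfView]:
    """Bind per-field channel files listed in a manifest CSV into records.

    Expects columns ``id``, ``dapi_path``, ``fitc_path``; relative paths
    resolve against the manifest's directory.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    root = manifest_csv.parent
    fovs = []
    for _, row in df.iterrows():
        dapi = read_channel(root / row["dapi_path"], "dapi")
        fitc = read_channel(root / row["fitc_path"], "fitc")
        fovs.append(FieldOfView(dapi=dapi, fitc=fitc, field_id=str(row["id"])))
    return fovs
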