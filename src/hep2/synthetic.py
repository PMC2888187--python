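"""Seeded two-channel synthetic HEp-2 fields with known ground truth.

Every downstream stage (QC, segmentation, descriptors, interpretation) is
exercised against fields rendered here, because no public micrograph set
accompanies the method.  A field consists of a DAPI chromatin channel
(elliptical interphase nuclei plus bright condensed metaphase plates) and
a FITC autoantibody channel realizing one staining pattern:

========================  =====================================================
pattern                   FITC realization
========================  =====================================================
negative                  background only
homogeneous               uniform nuclear fill; metaphase chromatin stained
speckled_fine             dense small speckles (sigma 1 px) over diffuse fill
speckled_coarse           fewer, larger speckles (sigma 2.5 px), stronger fill
nucleolar                 2-4 bright nucleolar blobs, weak diffuse nucleus
centromere                ``dot_count`` discrete dots; dotted metaphase plate
nuclear_dots              few (< 30) discrete dots, dark nucleoplasm
cytoplasmic               stained cytoplasm annulus, dark nucleus
nuclear_membrane          bright 2-3 px rim at the nuclear envelope
golgi                     single bright perinuclear crescent
========================  =====================================================

``nuclear_membrane`` and ``golgi`` exist to reproduce documented confusion
behaviour of rule-based readers (rim staining read as speckled; Golgi read
as cytoplasmic); they are not part of the six reportable main patterns.

All randomness flows from ``FieldSpec.seed`` through one Generator, so an
identical spec renders bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
from scipy import ndimage as ndi

from .imaging import ChannelImage, FieldOfView

__all__ = [
    "PATTERNS",
    "DOT_PATTERNS",
    "MAIN_PATTERNS",
    "FieldSpec",
    "GroundTruth",
    "CohortClass",
    "PlacementError",
    "render_field",
    "generate_cohort",
    "write_field",
]

PATTERNS = (
    "negative", "homogeneous", "speckled_fine", "speckled_coarse", "nucleolar",
    "centromere", "nuclear_dots", "cytoplasmic", "nuclear_membrane", "golgi",
)
DOT_PATTERNS = ("centromere", "nuclear_dots")
#: The six reportable main patterns (speckled realized at two scales).
MAIN_PATTERNS = ("cytoplasmic", "homogeneous", "speckled", "nucleolar",
                 "centromere", "nuclear_dots")

# Rendering constants (16-bit scale).  Chosen once as a conventional
# fluorescence contrast regime: low background, mid-range DAPI, FITC
# amplitude scaled by intensity_level.
BACKGROUND = 500.0
DAPI_INTERPHASE = 12000.0
DAPI_MITOTIC_FACTOR = 2.2     # gives the mitosis detector a >=2x contrast
FITC_AMP = 30000.0
HOMOG_PLATE_FACTOR = 1.15     # metaphase chromatin stains slightly stronger
DOT_ERODE_PX = 3              # dots are placed clear of the nuclear rim


class PlacementError(RuntimeError):
    """Cells cannot be placed within the overlap budget."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field; same spec + seed => same bytes."""

    width: int = 320
    height: int = 320
    n_interphase: int = 15
    n_mitotic: int = 2
    pattern: str = "homogeneous"
    intensity_level: float = 0.7
    dot_count: int = 0
    noise_sd: float = 300.0
    defocus_sigma: float = 0.0
    artifact: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.n_interphase < 0 or self.n_mitotic < 0:
            raise ValueError("cell counts must be non-negative")
        if not 0.0 <= self.intensity_level <= 1.0:
            raise ValueError("intensity_level must lie in [0, 1]")
        if self.dot_count and self.pattern not in DOT_PATTERNS:
            raise ValueError("dot_count > 0 only valid for dot patterns")
        if self.dot_count < 0:
            raise ValueError("dot_count must be non-negative")
        if self.artifact not in ("none", "streak", "blob"):
            raise ValueError("artifact must be none|streak|blob")

    @property
    def effective_dot_count(self) -> int:
        if self.dot_count:
            return self.dot_count
        if self.pattern == "centromere":
            return 45
        if self.pattern == "nuclear_dots":
            return 6
        return 0


@dataclass(frozen=True)
class GroundTruth:
    """Everything the renderer knows about a field."""

    nucleus_centers: tuple[tuple[float, float], ...]
    nucleus_labels: np.ndarray          # int label image, 0 = background
    mitotic_flags: tuple[bool, ...]     # per label (1-based order)
    pattern: str
    artifact_mask: np.ndarray           # bool
    dot_positions: tuple[tuple[tuple[int, int], ...], ...]  # per label
    fitc_noiseless: np.ndarray          # float signal before noise/blur

    @property
    def n_labels(self) -> int:
        return int(self.nucleus_labels.max())


@dataclass(frozen=True)
class CohortClass:
    """One stratum of a synthetic cohort."""

    pattern: str
    intensity: float | tuple[float, float] = 0.7
    dot_count: int = 0


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_mask(shape, center, axes, angle):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _bar_mask(shape, center, length, width, angle):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)


def _place_objects(rng, shape, n_interphase, n_mitotic, axes_range,
                   max_overlap=0.2, max_attempts=1000):
    """Rejection-sample ellipse/bar placements within the overlap budget."""
    h, w = shape
    occupied = np.zeros(shape, bool)
    masks, centers, mitotic = [], [], []
    jobs = [False] * n_interphase + [True] * n_mitotic
    for is_mit in jobs:
        placed = False
        for _ in range(max_attempts):
            margin = 18
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            angle = rng.uniform(0, np.pi)
            if is_mit:
                length = rng.uniform(20, 28)
                width_ = rng.uniform(6, 9)
                mask = _bar_mask(shape, center, length, width_, angle)
            else:
                axes = (rng.uniform(*axes_range), rng.uniform(*axes_range))
                mask = _ellipse_mask(shape, center, axes, angle)
            area = int(mask.sum())
            if area == 0:
                continue
            if (mask & occupied).sum() / area <= max_overlap:
                occupied |= mask
                masks.append(mask)
                centers.append(center)
                mitotic.append(is_mit)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place object {len(masks) + 1} within the "
                f"{max_overlap:.0%} overlap budget after {max_attempts} attempts"
            )
    return masks, centers, mitotic


def _sample_points(rng, mask, n, min_sep, max_attempts=20000, avoid=()):
    """n points inside ``mask`` with pairwise distance >= min_sep.

    ``avoid`` lists previously placed points (e.g. dots of an
    overlapping neighbour) that must also be respected, so local maxima
    stay resolvable across touching cells.
    """
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise PlacementError("empty placement region for dots")
    pts: list[tuple[int, int]] = []
    taken = list(avoid)
    for _ in range(max_attempts):
        if len(pts) == n:
            break
        r, c = coords[rng.integers(len(coords))]
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in pts) and \
           all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in taken):
            pts.append((int(r), int(c)))
    if len(pts) < n:
        raise PlacementError(f"placed only {len(pts)}/{n} dots at separation {min_sep}")
    return pts


def _add_gaussian_spots(img, points, sigma, amp):
    """Accumulate unit-height Gaussian bumps at integer positions."""
    half = max(2, int(np.ceil(3 * sigma)))
    ax = np.arange(-half, half + 1, dtype=np.float64)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    h, w = img.shape
    for r, c in points:
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        img[r0:r1, c0:c1] += amp * kernel[r0 - (r - half): r1 - (r - half),
                                          c0 - (c - half): c1 - (c - half)]


def _disk(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return ax[:, None] ** 2 + ax[None, :] ** 2 <= radius**2


# ---------------------------------------------------------------------------
# FITC pattern painters (relative units; 1.0 = intensity_level * FITC_AMP)

def _paint_fitc(rng, spec, masks, mitotic, all_nuclei):
    shape = (spec.height, spec.width)
    sig = np.zeros(shape, np.float64)
    dot_positions: list[tuple[tuple[int, int], ...]] = []
    pat = spec.pattern

    if pat == "negative":
        # negative sera still show faint nonspecific binding across the
        # whole cell (nucleus and cytoplasm alike); intensity_level is
        # expected in ~U(0, 0.1) for a normal-donor population.  Painted
        # once over the union so overlapping cells do not double up.
        union = ndi.binary_dilation(all_nuclei, _disk(6))
        sig[union] = 1.0
        return sig, tuple(() for _ in masks)

    if pat == "cytoplasmic":
        # one union paint so adjacent cells' cytoplasm does not double up
        inter = np.zeros(shape, bool)
        for mask, is_mit in zip(masks, mitotic):
            if not is_mit:
                inter |= mask
        cyto = ndi.binary_dilation(inter, _disk(8)) & ~all_nuclei
        sig[cyto] = 0.9
        sig[inter] = 0.08
        return sig, tuple(() for _ in masks)

    all_dots: list[tuple[int, int]] = []  # cross-cell dot separation

    def near_mask(mask, pad=6):
        rows, cols = np.nonzero(mask)
        r0, r1 = rows.min() - pad, rows.max() + pad
        c0, c1 = cols.min() - pad, cols.max() + pad
        return [p for p in all_dots if r0 <= p[0] <= r1 and c0 <= p[1] <= c1]

    for mask, is_mit in zip(masks, mitotic):
        dots: tuple[tuple[int, int], ...] = ()
        if pat == "negative":
            pass
        elif pat == "homogeneous":
            sig[mask] += HOMOG_PLATE_FACTOR if is_mit else 1.0
        elif pat in ("speckled_fine", "speckled_coarse"):
            if not is_mit:  # metaphase chromatin stays dark
                area = mask.sum()
                if pat == "speckled_fine":
                    n, sigma, diffuse = max(4, int(area / 8)), 1.0, 0.30
                else:
                    n, sigma, diffuse = max(3, int(area / 35)), 2.5, 0.50
                sig[mask] += diffuse
                coords = np.argwhere(mask)
                pts = coords[rng.integers(len(coords), size=n)]
                # speckles are intranuclear: clip the bump tails to the
                # nucleus so neighbouring plates/cells see no leakage
                bumps = np.zeros_like(sig)
                _add_gaussian_spots(bumps, pts, sigma, 1.0)
                sig[mask] += bumps[mask]
        elif pat == "nucleolar":
            if not is_mit:
                sig[mask] += 0.12
                interior = ndi.binary_erosion(mask, _disk(6))
                region = interior if interior.any() else mask
                n_blobs = int(rng.integers(2, 5))
                try:
                    centers = _sample_points(rng, region, n_blobs, min_sep=9)
                except PlacementError:
                    centers = _sample_points(rng, region, 1, min_sep=7)
                for r, c in centers:
                    radius = int(rng.integers(4, 6))
                    blob = np.zeros(shape, bool)
                    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
                    blob = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
                    sig[blob & mask] += 1.0
        elif pat in DOT_PATTERNS:
            if is_mit:
                if pat == "centromere":  # dotted metaphase chromatin
                    interior = ndi.binary_erosion(mask, _disk(1))
                    pts = _sample_points(rng, interior if interior.any() else mask,
                                         8, 2.2, avoid=near_mask(mask))
                    _add_gaussian_spots(sig, pts, 0.9, 1.0)
                    dots = tuple(pts)
                    all_dots.extend(pts)
            else:
                interior = ndi.binary_erosion(mask, _disk(DOT_ERODE_PX))
                n = spec.effective_dot_count
                sigma = 0.9 if pat == "centromere" else 1.1
                sep = 2.2 if pat == "centromere" else 4.0
                pts = _sample_points(rng, interior if interior.any() else mask,
                                     n, sep, avoid=near_mask(mask))
                _add_gaussian_spots(sig, pts, sigma, 1.0)
                dots = tuple(pts)
                all_dots.extend(pts)
        elif pat == "cytoplasmic":
            if not is_mit:
                cyto = ndi.binary_dilation(mask, _disk(8)) & ~all_nuclei
                sig[cyto] += 0.9
                sig[mask] += 0.08
        elif pat == "nuclear_membrane":
            if not is_mit:
                rim = mask & ~ndi.binary_erosion(mask, _disk(2))
                sig[mask] += 0.10
                sig[rim] += 0.90
        elif pat == "golgi":
            if not is_mit:
                ring = ndi.binary_dilation(mask, _disk(5)) & ~all_nuclei
                rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
                center = ndi.center_of_mass(mask)
                theta = np.arctan2(rr - center[0], cc - center[1])
                phi0 = rng.uniform(-np.pi, np.pi)
                dtheta = np.angle(np.exp(1j * (theta - phi0)))
                crescent = ring & (np.abs(dtheta) <= np.deg2rad(120))
                sig[crescent] += 1.0
                sig[mask] += 0.05
        dot_positions.append(dots)
    return sig, tuple(dot_positions)


# ---------------------------------------------------------------------------

def _paint_artifact(rng, spec, dapi, fitc):
    shape = (spec.height, spec.width)
    mask = np.zeros(shape, bool)
    if spec.artifact == "none":
        return mask
    if spec.artifact == "streak":
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
        angle = rng.uniform(0, np.pi)
        offset = rng.uniform(0.3, 0.7)
        r0, c0 = offset * shape[0], offset * shape[1]
        dist = np.abs((rr - r0) * np.cos(angle) + (cc - c0) * np.sin(angle))
        mask = dist <= 3.0
    else:  # blob
        r = rng.uniform(0.25, 0.75, size=2) * shape
        radius = rng.uniform(18, 30)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
        mask = (rr - r[0]) ** 2 + (cc - r[1]) ** 2 <= radius**2
    level = 0.95 * 65535
    fitc[mask] = np.maximum(fitc[mask], level)
    dapi[mask] = np.maximum(dapi[mask], level)
    return mask


def render_field(spec: FieldSpec) -> tuple[FieldOfView, GroundTruth]:
    """Render one two-channel field and its ground truth.

    Raises :class:`PlacementError` when geometry is infeasible rather
    than silently truncating the cell count.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    # dot and nucleolar patterns need larger nuclei so their foci fit
    if spec.pattern in (*DOT_PATTERNS, "nucleolar"):
        axes_range = (13.0, 16.0)
    else:
        axes_range = (7.5, 15.0)
    masks, centers, mitotic = _place_objects(
        rng, shape, spec.n_interphase, spec.n_mitotic, axes_range
    )

    labels = np.zeros(shape, np.int32)
    for i, mask in enumerate(masks, start=1):
        labels[mask & (labels == 0)] = i

    dapi = np.full(shape, BACKGROUND)
    for mask, is_mit in zip(masks, mitotic):
        # per-cell jitter on interphase only: plates must keep the
        # documented >= 2x contrast over the interphase median
        jitter = 1.0 if is_mit else rng.uniform(0.85, 1.15)
        level = DAPI_INTERPHASE * (DAPI_MITOTIC_FACTOR if is_mit else 1.0)
        dapi[mask] = BACKGROUND + level * jitter

    all_nuclei = labels > 0
    sig, dot_positions = _paint_fitc(rng, spec, masks, mitotic, all_nuclei)
    amp = spec.intensity_level * FITC_AMP
    fitc = BACKGROUND + amp * sig
    fitc_noiseless = fitc.copy()

    artifact_mask = _paint_artifact(rng, spec, dapi, fitc)

    if spec.defocus_sigma > 0:
        dapi = ndi.gaussian_filter(dapi, spec.defocus_sigma)
        fitc = ndi.gaussian_filter(fitc, spec.defocus_sigma)
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, spec.noise_sd, shape)
        fitc = fitc + rng.normal(0.0, spec.noise_sd, shape)

    dapi = np.clip(np.round(dapi), 0, 65535).astype(np.uint16)
    fitc = np.clip(np.round(fitc), 0, 65535).astype(np.uint16)

    fov = FieldOfView(
        dapi=ChannelImage(dapi, 16, "dapi"),
        fitc=ChannelImage(fitc, 16, "fitc"),
        field_id=f"synthetic-{spec.seed}",
    )
    truth = GroundTruth(
        nucleus_centers=tuple((float(r), float(c)) for r, c in centers),
        nucleus_labels=labels,
        mitotic_flags=tuple(mitotic),
        pattern=spec.pattern,
        artifact_mask=artifact_mask,
        dot_positions=dot_positions,
        fitc_noiseless=fitc_noiseless,
    )
    return fov, truth


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(
    n_samples: int,
    class_mix: list[tuple[float, CohortClass]],
    seed: int,
    base_spec: FieldSpec | None = None,
    out_dir: str | Path | None = None,
):
    """Draw a labelled cohort of fields from a pattern/intensity mixture.

    ``class_mix`` lists (probability, stratum) pairs summing to 1; each
    sample's stratum is a multinomial draw.  An ``intensity`` given as a
    (lo, hi) tuple is sampled uniformly per sample.  Returns a list of
    (spec, FieldOfView, GroundTruth) and a manifest DataFrame; when
    ``out_dir`` is given, images, truths and ``manifest.csv`` are written.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    probs = np.array([p for p, _ in class_mix], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("class mix probabilities must sum to 1")
    base = base_spec or FieldSpec()
    rng = np.random.default_rng(seed)
    choices = rng.choice(len(class_mix), size=n_samples, p=probs)

    records, rows = [], []
    for i, ci in enumerate(choices):
        cls = class_mix[ci][1]
        if isinstance(cls.intensity, tuple):
            level = float(rng.uniform(*cls.intensity))
        else:
            level = float(cls.intensity)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base, pattern=cls.pattern, intensity_level=level,
            dot_count=cls.dot_count, seed=sample_seed,
        )
        fov, truth = render_field(spec)
        sample_id = f"s{i:04d}"
        records.append((spec, fov, truth))
        rows.append({
            "id": sample_id, "pattern": cls.pattern,
            "intensity_level": level, "seed": sample_seed,
            "dapi_path": f"{sample_id}_dapi.tif", "fitc_path": f"{sample_id}_fitc.tif",
        })
        if out_dir is not None:
            write_field(fov, truth, out_dir, sample_id)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return records, manifest


def write_field(fov: FieldOfView, truth: GroundTruth, out_dir, sample_id: str) -> None:
    """Write TIFF channel pair, 16-bit label PNG and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{sample_id}_dapi.tif", fov.dapi.pixels.astype(np.uint16))
    tifffile.imwrite(out / f"{sample_id}_fitc.tif", fov.fitc.pixels.astype(np.uint16))
    iio.imwrite(out / f"{sample_id}_labels.png", truth.nucleus_labels.astype(np.uint16))
    meta = {
        "pattern": truth.pattern,
        "nucleus_centers": [list(c) for c in truth.nucleus_centers],
        "mitotic_flags": list(truth.mitotic_flags),
        "dot_positions": [[list(p) for p in dots] for dots in truth.dot_positions],
    }
    (out / f"{sample_id}_truth.json").write_text(json.dumps(meta))
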