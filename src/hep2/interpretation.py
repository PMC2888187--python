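"""Reactivity index, calibration, and the hierarchical classification chain.

A sample is interpreted in three stages, mirroring expert reading:

(a) **positivity** — a reactivity index (RI) combines absolute image
    intensity, foreground/background contrast and grey-level richness of
    the exposure-normalized FITC image; thresholds calibrated on a
    negative (normal-donor) population split negative / weak positive /
    positive, the three classes corresponding to titer bands (< 1:80,
    1:80-1:160, >= 1:320) in the visual protocol.

(b) **localization** — cytoplasmic when the cytoplasmic ring clearly
    out-stains the nucleus (the reader deliberately emphasizes strong
    cytoplasmic signal over coincident nuclear staining), mitotic
    chromatin when only the metaphase plate stains, else nuclear.

(c) **nuclear pattern** — a fixed rule cascade over aggregated per-cell
    descriptors: many dots confirmed on metaphase chromatin => centromere;
    a few discrete dots on a dark nucleoplasm => multiple nuclear dots;
    few bright blobs over a weak diffuse nucleus => nucleolar; stained
    metaphase chromatin => homogeneous; high intra-nuclear variation =>
    speckled.  Every rule evaluation is logged to a rule trace.

The RI combination is multiplicative (value = 100 · intensity · contrast ·
richness): a blank image scores exactly 0 and no single component can be
bypassed.  Two documented confusion behaviours of the emulated reader are
intentionally preserved, not corrected: nuclear-envelope rim staining is
reported as speckled, and Golgi staining as cytoplasmic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import median

import numpy as np

from .imaging import ChannelImage, FieldOfView, qc_tiles, normalize_exposure
from .segmentation import segment_nuclei, extract_cells, UnusableFieldError
from .descriptors import (
    DescriptorVector, MetaphaseSignal, compute_descriptors, metaphase_signal,
)

__all__ = [
    "ReactivityIndex",
    "CalibrationModel",
    "SampleResult",
    "PipelineConfig",
    "UnevaluableSampleError",
    "compute_ri",
    "calibrate",
    "classify_positivity",
    "classify_localization",
    "classify_nuclear_pattern",
    "interpret_field",
    "interpret_sample",
    "sample_ri",
]

POSITIVITY_LEVELS = ("negative", "weak_positive", "positive")
LOCALIZATIONS = ("nuclear", "cytoplasmic", "mitotic_chromatin", "none")
NUCLEAR_PATTERNS = ("cytoplasmic", "homogeneous", "speckled", "nucleolar",
                    "centromere", "nuclear_dots", "none")


class UnevaluableSampleError(RuntimeError):
    """Every field of the sample failed QC; the sample has no result."""


@dataclass(frozen=True)
class ReactivityIndex:
    """Positivity score and its three multiplicative components."""

    value: float
    intensity_component: float
    contrast_component: float
    greyscale_richness: float

    def __post_init__(self) -> None:
        for name in ("intensity_component", "contrast_component", "greyscale_richness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        expected = 100.0 * self.intensity_component * self.contrast_component \
            * self.greyscale_richness
        if abs(self.value - expected) > 1e-6 * max(1.0, expected):
            raise ValueError("value must equal 100 * product of components")


@dataclass(frozen=True)
class CalibrationModel:
    """Positivity thresholds derived from a negative population."""

    negative_threshold: float
    positive_threshold: float
    source_n: int
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.negative_threshold < self.positive_threshold:
            raise ValueError("thresholds must satisfy 0 < negative < positive")


@dataclass(frozen=True)
class SampleResult:
    """Hierarchical call with rule trace."""

    positivity: str
    localization: str
    pattern: str
    ri: ReactivityIndex
    rule_trace: tuple[str, ...]
    fields_used: int

    def __post_init__(self) -> None:
        if self.positivity not in POSITIVITY_LEVELS:
            raise ValueError(f"bad positivity {self.positivity!r}")
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"bad localization {self.localization!r}")
        if self.pattern not in NUCLEAR_PATTERNS:
            raise ValueError(f"bad pattern {self.pattern!r}")
        if self.positivity == "negative" and self.pattern != "none":
            raise ValueError("negative samples carry no pattern")

    def to_dict(self) -> dict:
        return {
            "positivity": self.positivity,
            "localization": self.localization,
            "pattern": self.pattern,
            "ri": {
                "value": self.ri.value,
                "intensity_component": self.ri.intensity_component,
                "contrast_component": self.ri.contrast_component,
                "greyscale_richness": self.ri.greyscale_richness,
            },
            "rule_trace": list(self.rule_trace),
            "fields_used": self.fields_used,
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the full chain, with documented defaults."""

    qc_grid: tuple[int, int] = (4, 4)
    qc_mad_k: float = 5.0
    qc_saturation_frac: float = 0.01
    min_area: int = 100
    ring_width: int = 5
    mitosis_m: float = 1.8
    calibration_percentile: float = 99.0
    calibration_ratio: float = 2.5
    cytoplasm_alpha: float = 1.2          # cytoplasm-over-nucleus emphasis
    centromere_min_dots: int = 30
    min_dots: int = 2
    punctate_max_diffuse: float = 0.15    # diffuse / dot-peak, background-subtracted
    nucleolar_max_blobs: int = 6
    nucleolar_min_rel_intensity: float = 2.0
    speckle_cv_threshold: float = 0.25

    def fingerprint(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


# ---------------------------------------------------------------------------
# Reactivity index

def compute_ri(
    fitc: ChannelImage,
    foreground_mask: np.ndarray,
    artifact_mask: np.ndarray | None = None,
    titer_gamma: float = 0.66,
    crest_percentile: float = 99.0,
) -> ReactivityIndex:
    """RI of an exposure-normalized FITC image.

    intensity: the highest non-artifact foreground signal on the
    exposure-corrected absolute scale (the normalized image divided by
    its accumulated exposure gain, relative to the dtype range), raised
    to ``titer_gamma``.  Taking the maximum keeps sparse discrete
    patterns (nuclear dots, centromeres) visible, because their few
    bright foci *are* the highest image signal the exposure control keys
    on.  The exponent maps the multiplicative titer scale onto the
    calibration's linear threshold ratio: the weakly-positive band spans
    a factor-4 titer range (1:80 to 1:320) that the two thresholds cover
    with a factor ``r`` (default 2.5), so gamma = ln r / ln 4 ≈ 0.66.

    contrast: RMS deviation of the stained crest — the top percentile of
    foreground pixels — from the background mean, relative to range, on
    the normalized image.  Restricting to the crest makes the component
    measure how strongly the stained structure stands out rather than
    how much of the mask is stained, so sparse foci are not diluted by
    dark nucleoplasm or cytoplasm inside the measurement masks.

    richness: occupied integer grey levels / total levels on the
    normalized image.  All components use non-artifact pixels only.
    """
    px = fitc.pixels.astype(np.float64)
    valid = np.ones(px.shape, bool) if artifact_mask is None else ~np.asarray(artifact_mask, bool)
    if not valid.any():
        raise ValueError("image fully masked as artifact")
    fg = px[np.asarray(foreground_mask, bool) & valid]
    bg = px[~np.asarray(foreground_mask, bool) & valid]
    if fg.size == 0:
        raise ValueError("empty foreground")
    rng_max = float(fitc.max_value)
    intensity = min(1.0, float(fg.max()) / (rng_max * fitc.exposure_gain)) ** titer_gamma
    mu_bg = float(bg.mean()) if bg.size else 0.0
    crest = fg[fg >= np.percentile(fg, crest_percentile)]
    contrast = min(1.0, float(np.sqrt(np.mean((crest - mu_bg) ** 2))) / rng_max)
    occupied = np.unique(np.round(px[valid]).astype(np.int64)).size
    richness = occupied / (fitc.max_value + 1)
    value = 100.0 * intensity * contrast * richness
    return ReactivityIndex(value, intensity, contrast, richness)


def calibrate(
    negative_ris,
    percentile: float = 99.0,
    ratio: float = 2.5,
) -> CalibrationModel:
    """Thresholds from the RI distribution of a negative population.

    negative_threshold is the given percentile (default 99th) of the
    negative RIs; positive_threshold is ``ratio`` times that.  Requires
    n >= 30; below 200 a warning notes reduced calibration precision.
    """
    values = np.asarray(list(negative_ris), dtype=np.float64)
    if values.size < 30:
        raise ValueError("calibration needs at least 30 negative samples")
    if np.unique(values).size < 2:
        raise ValueError("degenerate negative RI distribution (constant values)")
    if values.size < 200:
        warnings.warn(
            f"calibrating on {values.size} negatives; 200 recommended", stacklevel=2
        )
    neg = float(np.percentile(values, percentile))
    if neg <= 0:
        raise ValueError("non-positive negative threshold")
    return CalibrationModel(
        negative_threshold=neg,
        positive_threshold=neg * ratio,
        source_n=int(values.size),
        method=f"p{percentile:g} of negative population; positive = {ratio:g} x negative",
    )


def classify_positivity(ri: ReactivityIndex | float, cal: CalibrationModel) -> str:
    """Three-class call; boundary values go to the higher class."""
    value = ri.value if isinstance(ri, ReactivityIndex) else float(ri)
    if value >= cal.positive_threshold:
        return "positive"
    if value >= cal.negative_threshold:
        return "weak_positive"
    return "negative"


# ---------------------------------------------------------------------------
# Rule-based classification over aggregated descriptors

@dataclass
class FieldAggregate:
    """Medians over interphase cells plus field context for the rules."""

    nuclear_median: float
    ring_median: float
    background_median: float
    dot_count: float
    dot_peak_mean: float
    blob_count: float
    blob_rel_intensity: float
    cv: float
    metaphase: MetaphaseSignal

    @classmethod
    def from_descriptors(
        cls,
        descriptors: list[DescriptorVector],
        meta: MetaphaseSignal,
        background_median: float,
    ) -> "FieldAggregate":
        if not descriptors:
            raise ValueError("no interphase cells to aggregate")
        med = lambda attr: float(median(getattr(d, attr) for d in descriptors))
        return cls(
            nuclear_median=med("nucleus_median"),
            ring_median=med("ring_median"),
            background_median=background_median,
            dot_count=med("dot_count"),
            dot_peak_mean=med("dot_peak_mean"),
            blob_count=med("blob_count"),
            blob_rel_intensity=med("blob_rel_intensity"),
            cv=med("coefficient_of_variation"),
            metaphase=meta,
        )


def classify_localization(
    agg: FieldAggregate, config: PipelineConfig = PipelineConfig()
) -> tuple[str, list[str]]:
    """Stage (b): nuclear / cytoplasmic / mitotic_chromatin."""
    trace: list[str] = []
    ratio = agg.ring_median / max(agg.nuclear_median, 1e-9)
    cyto = ratio > config.cytoplasm_alpha
    trace.append(
        f"localization.cytoplasmic: ring/nuclear={ratio:.3f} "
        f"> alpha={config.cytoplasm_alpha} -> {cyto}"
    )
    if cyto:
        return "cytoplasmic", trace
    meta = agg.metaphase
    nuclear_signal = agg.nuclear_median - agg.background_median
    if not meta.indeterminate and meta.chromatin_positive:
        plate_signal = meta.ratio * max(agg.nuclear_median, 1e-9) - agg.background_median
        only_plate = nuclear_signal < 0.2 * max(plate_signal, 1e-9)
        trace.append(
            f"localization.mitotic_chromatin: nuclear_signal={nuclear_signal:.1f} "
            f"< 0.2*plate_signal={0.2 * plate_signal:.1f} -> {only_plate}"
        )
        if only_plate:
            return "mitotic_chromatin", trace
    if meta.indeterminate:
        trace.append("localization.nuclear: metaphase indeterminate (reduced confidence)")
    else:
        trace.append("localization.nuclear: default")
    return "nuclear", trace


def classify_nuclear_pattern(
    agg: FieldAggregate, config: PipelineConfig = PipelineConfig()
) -> tuple[str, list[str]]:
    """Stage (c): fixed rule cascade over the aggregated descriptors.

    Rule order: centromere, nuclear dots, nucleolar, homogeneous,
    speckled.  A dot count at the centromere boundary goes to centromere
    only with dotted metaphase confirmation, else to nuclear dots; a high
    dot count *without* confirmation reads as dense speckling and falls
    through to the texture rules.  When the metaphase state is
    indeterminate, homogeneous-vs-speckled falls back to texture only.
    """
    trace: list[str] = []
    meta = agg.metaphase
    dots = agg.dot_count

    dotted = (not meta.indeterminate) and meta.chromatin_dotted
    r1 = dots >= config.centromere_min_dots and dotted
    trace.append(
        f"pattern.centromere: median_dots={dots:.0f} >= {config.centromere_min_dots} "
        f"and metaphase_dotted={dotted} -> {r1}"
    )
    if r1:
        return "centromere", trace

    diffuse = agg.nuclear_median - agg.background_median
    peak = agg.dot_peak_mean - agg.background_median
    punctate = peak > 0 and diffuse < config.punctate_max_diffuse * peak
    no_blobs = agg.blob_count < 1  # large foci are nucleolar, not dots
    r2 = config.min_dots <= dots <= config.centromere_min_dots and punctate and no_blobs
    trace.append(
        f"pattern.nuclear_dots: {config.min_dots} <= median_dots={dots:.0f} "
        f"<= {config.centromere_min_dots} and punctate={punctate} "
        f"and no_large_blobs={no_blobs} -> {r2}"
    )
    if r2:
        return "nuclear_dots", trace

    r3 = (1 <= agg.blob_count <= config.nucleolar_max_blobs
          and agg.blob_rel_intensity >= config.nucleolar_min_rel_intensity)
    trace.append(
        f"pattern.nucleolar: 1 <= median_blobs={agg.blob_count:.0f} <= "
        f"{config.nucleolar_max_blobs} and rel_intensity={agg.blob_rel_intensity:.2f} "
        f">= {config.nucleolar_min_rel_intensity} -> {r3}"
    )
    if r3:
        return "nucleolar", trace

    if meta.indeterminate:
        speckled = agg.cv >= config.speckle_cv_threshold
        trace.append(
            "pattern.fallback: metaphase indeterminate, texture-only "
            f"(reduced confidence): cv={agg.cv:.3f} -> "
            f"{'speckled' if speckled else 'homogeneous'}"
        )
        return ("speckled" if speckled else "homogeneous"), trace

    r4 = meta.chromatin_positive
    trace.append(f"pattern.homogeneous: metaphase_positive={r4} (ratio={meta.ratio:.2f}) -> {r4}")
    if r4:
        return "homogeneous", trace

    r5 = agg.cv >= config.speckle_cv_threshold
    trace.append(
        f"pattern.speckled: cv={agg.cv:.3f} >= {config.speckle_cv_threshold} -> {r5}"
    )
    if r5:
        return "speckled", trace
    trace.append("pattern.default: weak diffuse nuclear staining -> homogeneous")
    return "homogeneous", trace


# ---------------------------------------------------------------------------
# Field and sample pipelines

@dataclass
class FieldInterpretation:
    ri: ReactivityIndex
    aggregate: FieldAggregate | None
    trace: list[str]


def interpret_field(
    fov: FieldOfView, config: PipelineConfig = PipelineConfig()
) -> FieldInterpretation:
    """Run QC, normalization, segmentation and description on one field."""
    qc = qc_tiles(
        fov.fitc, grid=config.qc_grid, mad_k=config.qc_mad_k,
        saturation_frac=config.qc_saturation_frac,
    )
    if not qc.usable:
        raise UnusableFieldError("field failed tile QC")
    fitc_n = normalize_exposure(fov.fitc, qc.artifact_mask)
    labels = segment_nuclei(fov.dapi, qc, min_area=config.min_area)
    cells = extract_cells(labels, fov.dapi, ring_width=config.ring_width,
                          mitosis_m=config.mitosis_m)

    foreground = labels > 0
    for c in cells:
        r0, c0 = c.offset
        h, w = c.cytoplasm_ring.shape
        foreground[r0:r0 + h, c0:c0 + w] |= c.cytoplasm_ring
    if not foreground.any():
        foreground = fitc_n.pixels > np.percentile(fitc_n.pixels, 99)
    ri = compute_ri(fitc_n, foreground, qc.artifact_mask)

    interphase = [c for c in cells if not c.is_mitotic]
    aggregate = None
    trace: list[str] = []
    if interphase:
        fov_n = FieldOfView(dapi=fov.dapi, fitc=fitc_n, field_id=fov.field_id)
        descs = [compute_descriptors(c, fov_n) for c in interphase]
        meta = metaphase_signal(cells, fitc_n)
        bg_mask = ~foreground & ~qc.artifact_mask
        bg_median = float(np.median(fitc_n.pixels[bg_mask])) if bg_mask.any() else 0.0
        aggregate = FieldAggregate.from_descriptors(descs, meta, bg_median)
    else:
        trace.append("field: no interphase cells segmented")
    return FieldInterpretation(ri=ri, aggregate=aggregate, trace=trace)


def sample_ri(
    fields: list[FieldOfView], config: PipelineConfig = PipelineConfig()
) -> float:
    """Median RI across usable fields (used for calibration cohorts)."""
    values = []
    for fov in fields:
        try:
            values.append(interpret_field(fov, config).ri.value)
        except UnusableFieldError:
            continue
    if not values:
        raise UnevaluableSampleError("no usable fields")
    return float(np.median(values))


def interpret_sample(
    fields: list[FieldOfView],
    cal: CalibrationModel,
    config: PipelineConfig = PipelineConfig(),
) -> SampleResult:
    """Full hierarchical call for one sample from its fields of view."""
    if not fields:
        raise ValueError("sample has no fields")
    interps: list[FieldInterpretation] = []
    for fov in fields:
        try:
            interps.append(interpret_field(fov, config))
        except UnusableFieldError:
            continue
    if not interps:
        raise UnevaluableSampleError("all fields failed QC")

    ris = [fi.ri for fi in interps]
    ri_values = [r.value for r in ris]
    ri_med = ris[int(np.argsort(ri_values)[len(ris) // 2])] if len(ris) % 2 else None
    if ri_med is None:  # even count: rebuild a consistent median record
        med_val = float(np.median(ri_values))
        closest = ris[int(np.argmin([abs(v - med_val) for v in ri_values]))]
        ri_med = closest
    trace: list[str] = [f"sample: median RI = {ri_med.value:.4f} over {len(interps)} fields"]

    positivity = classify_positivity(ri_med, cal)
    trace.append(
        f"positivity: RI={ri_med.value:.4f} vs thresholds "
        f"({cal.negative_threshold:.4f}, {cal.positive_threshold:.4f}) -> {positivity}"
    )
    if positivity == "negative":
        return SampleResult("negative", "none", "none", ri_med, tuple(trace), len(interps))

    calls: list[tuple[str, str, list[str]]] = []
    for fi in interps:
        if fi.aggregate is None:
            continue
        loc, loc_trace = classify_localization(fi.aggregate, config)
        if loc == "nuclear":
            pat, pat_trace = classify_nuclear_pattern(fi.aggregate, config)
        else:
            pat, pat_trace = ("cytoplasmic" if loc == "cytoplasmic" else "homogeneous"), []
        calls.append((loc, pat, loc_trace + pat_trace))
    if not calls:
        trace.append("no interphase cells in any field; localization indeterminate")
        return SampleResult(positivity, "nuclear", "speckled", ri_med, tuple(trace), len(interps))

    patterns = [pat for _, pat, _ in calls]
    locs = [loc for loc, _, _ in calls]
    pattern = max(set(patterns), key=lambda p: (patterns.count(p), -patterns.index(p)))
    localization = max(set(locs), key=lambda l: (locs.count(l), -locs.index(l)))
    winner = next(
        (tr for loc, pat, tr in calls if pat == pattern and loc == localization),
        calls[0][2],
    )
    trace.extend(winner)
    trace.append(f"sample: majority over {len(calls)} fields -> {localization}/{pattern}")
    return SampleResult(positivity, localization, pattern, ri_med, tuple(trace), len(interps))
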