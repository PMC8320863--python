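"""End-to-end nuclei detection: smoothing, gLoG bank, regional maxima,
threshold masking and mean-shift clustering, with named parameter presets.

The pipeline assumes the raw grayscale input renders nuclei dark
(``input_nuclei="dark"``, the plain H&E red channel) unless told otherwise.
An optional ``complement`` step inverts the intensities (the hardware's
complemented-red-channel convention).  The effective nuclei brightness after
the optional complement drives two coupled switches: the threshold polarity
(dark nuclei are kept where H < tau, bright where H >= tau) and the sign of
the gLoG response (the raw Laplacian kernel peaks on dark blobs, so bright
nuclei need the negated response).

Presets (printed parameter sets):

========  ============  =========  =====  ============
preset    Gaussian      gLoG size  tau    MS bandwidth
========  ============  =========  =====  ============
set1      7 x 7         25 x 25    155    8
set2      8 x 8         49 x 49    150    6
========  ============  =========  =====  ============
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateHistogramError, ParameterError
from .filtering import ConvolutionConfig, gaussian_smooth, glog_response_maps
from .imgio import extract_input_channel
from .kernels import Q2_14, FixedPointFormat, GLoGBankSpec, build_glog_filter_bank
from .msclustering import ClusterTable, MSConfig, mean_shift_cluster
from .regional_maxima import regional_maxima
from .threshold_mask import ThresholdConfig, collect_candidates, mask_response, otsu_threshold

logger = logging.getLogger("glogseed")

__all__ = ["PipelineConfig", "DetectionResult", "preset", "detect_nuclei"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the six-stage pipeline."""

    gaussian_size: int = 7
    gaussian_sigma: float = 1.0
    glog: GLoGBankSpec = field(default_factory=GLoGBankSpec)
    threshold: ThresholdConfig | None = None
    ms: MSConfig = field(default_factory=MSConfig)
    complement: bool = False
    input_nuclei: str = "dark"
    arithmetic: str = "float"
    border_mode: str = "replicate"
    fixed_format: FixedPointFormat = field(default=Q2_14)

    def __post_init__(self) -> None:
        if self.input_nuclei not in ("dark", "bright"):
            raise ParameterError("input_nuclei must be 'dark' or 'bright'")

    @property
    def nuclei_bright(self) -> bool:
        """Effective nuclei brightness after the optional complement."""
        return (self.input_nuclei == "bright") != self.complement

    def resolved_threshold(self) -> ThresholdConfig:
        """Threshold config with polarity coupled to the effective brightness."""
        polarity = "above" if self.nuclei_bright else "below"
        if self.threshold is None:
            return ThresholdConfig(tau="auto", polarity=polarity)
        return ThresholdConfig(tau=self.threshold.tau, polarity=polarity)

    def conv_config(self) -> ConvolutionConfig:
        return ConvolutionConfig(
            border_mode=self.border_mode,
            arithmetic=self.arithmetic,
            fixed_format=self.fixed_format,
        )


_PRESETS = {
    "set1": dict(
        gaussian_size=7,
        glog=GLoGBankSpec(kernel_size=25),
        threshold=ThresholdConfig(tau=155),
        ms=MSConfig(radius=8.0),
    ),
    "set2": dict(
        gaussian_size=8,
        glog=GLoGBankSpec(kernel_size=49),
        threshold=ThresholdConfig(tau=150),
        ms=MSConfig(radius=6.0),
    ),
}


def preset(name: str, **overrides) -> PipelineConfig:
    """Named parameter presets ``set1`` / ``set2`` (see the module table).

    Keyword overrides replace individual fields, e.g.
    ``preset("set1", complement=True)``.
    """
    if name not in _PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(PipelineConfig(**_PRESETS[name]), **overrides)


@dataclass
class DetectionResult:
    """Detected nuclei plus every retrievable intermediate stage."""

    nuclei: np.ndarray
    table: ClusterTable
    smoothed: np.ndarray
    response_maps: list[np.ndarray]
    maxima_maps: list[np.ndarray]
    mask: np.ndarray
    masked_maps: list[np.ndarray]
    candidates: np.ndarray
    tau: int | None
    config: PipelineConfig


def detect_nuclei(img: np.ndarray, cfg: PipelineConfig = PipelineConfig()) -> DetectionResult:
    """Run the six pipeline stages on a grayscale (or RGB) image.

    RGB inputs have their red channel extracted first (with the configured
    complement); grayscale inputs are complemented directly when requested.
    A constant smoothed image (no Otsu threshold definable) yields an empty
    mask and hence no detections.
    """
    img = np.asarray(img)
    if img.ndim == 3:
        gray = extract_input_channel(img, complement=cfg.complement)
    elif cfg.complement:
        gray = (255 - img.astype(np.int16)).astype(np.uint8)
    else:
        gray = img.astype(np.uint8)

    conv = cfg.conv_config()
    H = gaussian_smooth(gray, cfg.gaussian_size, cfg.gaussian_sigma, conv)
    bank = build_glog_filter_bank(cfg.glog)
    maps = glog_response_maps(H, bank, conv, negate=cfg.nuclei_bright)
    logger.info("computed %d gLoG response maps", len(maps))

    maxima = [regional_maxima(I) for I in maps]

    tcfg = cfg.resolved_threshold()
    tau: int | None
    try:
        tau = otsu_threshold(H) if tcfg.tau == "auto" else int(tcfg.tau)
        if tcfg.polarity == "below":
            T = (H < tau).astype(np.uint8)
        else:
            T = (H >= tau).astype(np.uint8)
    except DegenerateHistogramError:
        tau = None
        T = np.zeros_like(H, dtype=np.uint8)
    logger.info("threshold tau=%s polarity=%s mask pixels=%d", tau, tcfg.polarity, int(T.sum()))

    masked = [mask_response(R, T) for R in maxima]
    S = collect_candidates(masked)
    logger.info("seed candidates |S|=%d", len(S))

    nuclei, table = mean_shift_cluster(S, cfg.ms)
    logger.info("detected %d nuclei", len(nuclei))
    return DetectionResult(
        nuclei=nuclei,
        table=table,
        smoothed=H,
        response_maps=maps,
        maxima_maps=maxima,
        mask=T,
        masked_maps=masked,
        candidates=S,
        tau=tau,
        config=cfg,
    )
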