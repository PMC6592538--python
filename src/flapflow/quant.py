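"""Perfusion quantification: time-intensity curves, ingress, ingress rate, maps.

The two regional parameters are those reported by intra-operative
fluorescence systems:

* **ingress** (APU) — the absolute difference between the initial mean
  fluorescence of a region and its maximal value;
* **ingress rate** (APU/s) — the speed of the fluorescence rise ("blush
  rate"), computed here as ingress divided by the rise time from bolus onset
  to peak.  Onset is the first time the (lightly smoothed) curve exceeds
  baseline plus ``onset_k`` baseline standard deviations.

Peak and onset are detected on a centered 3-frame moving average so a single
noisy frame cannot set them, while the ingress difference itself uses the
raw curve, matching the parameter definition exactly.  Both parameters are
affine-equivariant: replacing F by a*F + b (a > 0) scales ingress and rate
by a and leaves onset and peak times unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateRiseError, GeometryError, ParameterError
from .frame_io import STANDARD_DURATION_S, FrameStack
from .zones import FlapGeometry, ZoneSet, bright_zone, partition_zones

__all__ = [
    "PerfusionCurve",
    "PerfusionParams",
    "ZonePerfusion",
    "PerfusionMap",
    "roi_mean_curve",
    "estimate_baseline",
    "compute_ingress",
    "compute_ingress_rate",
    "perfusion_params",
    "quantify_zones",
    "perfusion_map",
    "render_map",
]

DEFAULT_BASELINE_WINDOW = 4  # frames (1 s at 4 Hz); recording starts at injection
DEFAULT_SMOOTH_WIDTH = 3  # frames, centered moving average for onset/peak detection
DEFAULT_ONSET_K = 3.0  # onset threshold: baseline + k * baseline sd


@dataclass
class PerfusionCurve:
    """Mean fluorescence of a region over time."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ParameterError("times and values must be equal-length 1-D arrays")
        if self.times.size < 2:
            raise ParameterError("a curve needs at least two samples")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PerfusionParams:
    """Regional perfusion parameters.

    ``ingress`` is exactly the raw curve maximum minus the baseline (floored
    at zero); ``t_peak`` is the time of the first maximum of the smoothed
    curve; ``t_onset`` the detected bolus onset.
    """

    baseline: float
    ingress: float
    ingress_rate: float
    t_onset: float
    t_peak: float

    def as_dict(self) -> dict[str, float]:
        return {
            "baseline_apu": self.baseline,
            "ingress_apu": self.ingress,
            "ingress_rate_apu_s": self.ingress_rate,
            "t_onset_s": self.t_onset,
            "t_peak_s": self.t_peak,
        }


@dataclass
class ZonePerfusion:
    """Perfusion parameters of the whole flap (bright zone) and ROI1..ROI4."""

    whole_flap: PerfusionParams
    rois: dict[str, PerfusionParams]

    def as_dict(self) -> dict[str, dict[str, float]]:
        out = {"whole_flap": self.whole_flap.as_dict()}
        out.update({k: v.as_dict() for k, v in self.rois.items()})
        return out


@dataclass
class PerfusionMap:
    """Per-pixel ingress and time-to-peak images (dynamic color analysis).

    Values are defined inside the flap mask only; outside pixels are zero.
    """

    ingress: np.ndarray
    time_to_peak: np.ndarray
    mask: np.ndarray


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    return uniform_filter1d(values, size=width, mode="nearest")


def roi_mean_curve(stack: FrameStack, mask: np.ndarray) -> PerfusionCurve:
    """Spatial mean of the in-mask pixels at each frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise GeometryError(f"mask shape {mask.shape} does not match frames {stack.shape}")
    if not mask.any():
        raise GeometryError("ROI mask is empty")
    values = stack.frames[:, mask].mean(axis=1)
    return PerfusionCurve(times=stack.times, values=values)


def estimate_baseline(curve: PerfusionCurve, window: int = DEFAULT_BASELINE_WINDOW) -> float:
    """Initial mean fluorescence: mean of the first ``window`` samples."""
    if not (1 <= window <= len(curve)):
        raise ParameterError(f"baseline window {window} outside [1, {len(curve)}]")
    return float(curve.values[:window].mean())


def perfusion_params(
    curve: PerfusionCurve,
    window: int = DEFAULT_BASELINE_WINDOW,
    onset_k: float = DEFAULT_ONSET_K,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    rate_method: str = "rise",
) -> PerfusionParams:
    """Baseline, ingress, ingress rate and onset/peak times of a curve.

    ``rate_method`` is ``"rise"`` (ingress over onset-to-peak time, default),
    ``"max_slope"`` (maximum derivative of the smoothed curve) or ``"none"``
    (skip the rate; reported as 0).

    Raises
    ------
    DegenerateRiseError
        If ``rate_method="rise"`` and the curve has positive ingress but
        peaks at (or before) onset.
    """
    if len(curve) < window + 1:
        raise ParameterError("curve too short for the requested baseline window")
    if rate_method not in ("rise", "max_slope", "none"):
        raise ParameterError(f"unknown rate_method {rate_method!r}")
    baseline = estimate_baseline(curve, window)
    smoothed = _smooth(curve.values, smooth_width)
    peak_idx = int(np.argmax(smoothed))  # first maximum
    ingress = max(float(curve.values.max()) - baseline, 0.0)
    t_peak = float(curve.times[peak_idx])

    if ingress == 0.0:
        return PerfusionParams(baseline, 0.0, 0.0, float(curve.times[0]), t_peak)

    sd = float(np.std(curve.values[:window], ddof=1)) if window > 1 else 0.0
    threshold = baseline + onset_k * sd
    above = np.flatnonzero(smoothed > threshold)
    onset_idx = int(above[0]) if above.size else 0
    t_onset = float(curve.times[onset_idx])

    if rate_method == "none":
        rate = 0.0
    elif rate_method == "max_slope":
        rate = float(np.max(np.gradient(smoothed, curve.times)))
        rate = max(rate, 0.0)
    else:
        if peak_idx <= onset_idx:
            raise DegenerateRiseError(
                f"curve peaks at frame {peak_idx} <= onset frame {onset_idx}; rate undefined"
            )
        rate = ingress / (t_peak - t_onset)
    return PerfusionParams(baseline, ingress, rate, t_onset, t_peak)


def compute_ingress(curve: PerfusionCurve, window: int = DEFAULT_BASELINE_WINDOW) -> PerfusionParams:
    """Ingress of a curve: raw maximum minus the initial mean, floored at 0.

    Returns a :class:`PerfusionParams` with baseline, ingress and onset/peak
    times filled; the rate is not computed here (reported as 0).
    """
    return perfusion_params(curve, window=window, rate_method="none")


def compute_ingress_rate(
    curve: PerfusionCurve,
    window: int = DEFAULT_BASELINE_WINDOW,
    onset_k: float = DEFAULT_ONSET_K,
    rate_method: str = "rise",
) -> float:
    """Ingress rate (APU/s) of a curve; 0 when ingress is 0."""
    return perfusion_params(
        curve, window=window, onset_k=onset_k, rate_method=rate_method
    ).ingress_rate


def quantify_zones(
    stack: FrameStack,
    geometry: FlapGeometry,
    zones: ZoneSet | None = None,
    fraction: float = 0.2,
    window: int = DEFAULT_BASELINE_WINDOW,
    onset_k: float = DEFAULT_ONSET_K,
    rate_method: str = "rise",
) -> ZonePerfusion:
    """Whole-flap (bright zone) and per-ROI perfusion parameters.

    The stack should be standardized to the 20-s cut first; a warning is
    emitted otherwise so that parameters remain comparable across flaps.
    """
    if stack.duration > STANDARD_DURATION_S + 1e-9:
        warnings.warn(
            f"stack covers {stack.duration:.1f} s > {STANDARD_DURATION_S:.0f} s standard cut; "
            "trim before quantification for cross-flap comparability",
            stacklevel=2,
        )
    if zones is None:
        zones = partition_zones(geometry)
    bright = bright_zone(stack.frames, geometry.mask, fraction=fraction)

    def params(mask: np.ndarray) -> PerfusionParams:
        return perfusion_params(
            roi_mean_curve(stack, mask), window=window, onset_k=onset_k, rate_method=rate_method
        )

    return ZonePerfusion(
        whole_flap=params(bright),
        rois={name: params(m) for name, m in zones.as_dict().items()},
    )


def perfusion_map(
    stack: FrameStack,
    mask: np.ndarray,
    window: int = DEFAULT_BASELINE_WINDOW,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
) -> PerfusionMap:
    """Per-pixel ingress and time-to-peak (the dynamic color analysis input).

    The same definitions as the regional parameters, applied pixel-wise:
    ingress is the raw per-pixel maximum minus the per-pixel initial mean
    (floored at 0); time-to-peak is the time of the first maximum of the
    temporally smoothed course.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("flap mask is empty")
    if stack.n_frames < window + 1:
        raise ParameterError("stack too short for the requested baseline window")
    frames = stack.frames.astype(np.float64, copy=False)
    baseline = frames[:window].mean(axis=0)
    ingress = np.clip(frames.max(axis=0) - baseline, 0.0, None)
    smoothed = uniform_filter1d(frames, size=smooth_width, axis=0, mode="nearest") \
        if smooth_width > 1 else frames
    ttp = stack.times[np.argmax(smoothed, axis=0)]
    return PerfusionMap(
        ingress=np.where(mask, ingress, 0.0),
        time_to_peak=np.where(mask, ttp, 0.0),
        mask=mask,
    )


def render_map(pmap: PerfusionMap, path, which: str = "ingress", dpi: int = 100) -> None:
    """Render a perfusion map as a blue-to-red overlay PNG.

    Red marks the best-perfused pixels, blue the least perfused; pixels
    outside the flap are dark.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = pmap.ingress if which == "ingress" else pmap.time_to_peak
    shown = np.ma.masked_array(img, mask=~pmap.mask)
    fig, ax = plt.subplots(figsize=(img.shape[1] / dpi, img.shape[0] / dpi), dpi=dpi)
    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("black")
    ax.imshow(shown, cmap=cmap)
    ax.set_axis_off()
    fig.subplots_adjust(0, 0, 1, 1)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
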