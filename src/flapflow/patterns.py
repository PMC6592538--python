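"""Three-pattern classification of flap perfusion from the per-pixel map.

Clinically the patterns are read by eye from the dynamic color overlay:

* **type 1** — homogeneous perfusion of the perforator half that does not
  cross the midline;
* **type 2** — good perfusion only around the perforator emergence, poor
  elsewhere;
* **type 3** — homogeneous perfusion on both sides of the midline with poor
  peripheral flap ends.

This module replaces the visual read with an explicit, deterministic rule on
two kinds of features extracted from the per-pixel ingress image: zone
ingress ratios relative to the perforator zone (ROI2), and a
midline-crossing index — the mean ingress of a thin band just across the
midline divided by that of the mirror band on the perforator side.  All
features are ratios, so the classification is invariant to any positive
rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .quant import PerfusionMap
from .zones import FlapGeometry, ZoneSet

__all__ = [
    "PatternFeatures",
    "PatternLabel",
    "extract_pattern_features",
    "classify_pattern",
    "classify_map",
]

DEFAULT_TAU_CROSS = 0.5
DEFAULT_TAU_PERIPH = 0.5
DEFAULT_BAND_FRAC = 0.1  # midline band width, fraction of flap width per side


@dataclass(frozen=True)
class PatternFeatures:
    """Scale-free features of a perfusion map.

    ``r1``, ``r3``, ``r4`` are the mean per-pixel ingress of ROI1/3/4
    relative to ROI2; ``crossing_index`` compares the midline-adjacent bands
    (contralateral over ipsilateral).
    """

    r1: float
    r3: float
    r4: float
    crossing_index: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r1": self.r1,
            "r3": self.r3,
            "r4": self.r4,
            "crossing_index": self.crossing_index,
        }


@dataclass(frozen=True)
class PatternLabel:
    """A pattern assignment with the features and thresholds that produced it."""

    label: int
    features: PatternFeatures
    tau_cross: float
    tau_periph: float

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "features": self.features.as_dict(),
            "thresholds": {"tau_cross": self.tau_cross, "tau_periph": self.tau_periph},
        }


def extract_pattern_features(
    pmap: PerfusionMap,
    zones: ZoneSet,
    geometry: FlapGeometry,
    band_frac: float = DEFAULT_BAND_FRAC,
) -> PatternFeatures:
    """Zone ingress ratios and midline-crossing index of a perfusion map.

    Raises
    ------
    ParameterError
        If the perforator zone (ROI2) has zero mean ingress — features are
        undefined for a completely unperfused flap.
    """
    if not (0 < band_frac < 0.5):
        raise ParameterError("band_frac must be in (0, 0.5)")
    img = pmap.ingress

    def zone_mean(mask: np.ndarray) -> float:
        return float(img[mask].mean()) if mask.any() else 0.0

    m2 = zone_mean(zones.roi2)
    if m2 <= 0:
        raise ParameterError("ROI2 has zero mean ingress; pattern features undefined")
    r1 = zone_mean(zones.roi1) / m2
    r3 = zone_mean(zones.roi3) / m2
    r4 = zone_mean(zones.roi4) / m2

    c0, c1 = geometry.column_extent()
    bw = max(1, int(round(band_frac * (c1 - c0))))
    m = geometry.midline_col
    cols = np.arange(geometry.mask.shape[1])
    if geometry.perforator_side == "left":
        ipsi_band = (cols >= m - bw) & (cols < m)
        contra_band = (cols >= m) & (cols < m + bw)
    else:
        ipsi_band = (cols >= m) & (cols < m + bw)
        contra_band = (cols >= m - bw) & (cols < m)
    ipsi = geometry.mask & ipsi_band[None, :]
    contra = geometry.mask & contra_band[None, :]
    ipsi_mean = zone_mean(ipsi)
    if ipsi_mean <= 0:
        raise ParameterError("ipsilateral midline band has zero ingress; crossing undefined")
    crossing = zone_mean(contra) / ipsi_mean
    return PatternFeatures(r1=r1, r3=r3, r4=r4, crossing_index=crossing)


def classify_pattern(
    features: PatternFeatures,
    tau_cross: float = DEFAULT_TAU_CROSS,
    tau_periph: float = DEFAULT_TAU_PERIPH,
) -> PatternLabel:
    """Deterministic three-way decision rule.

    * crossing index >= ``tau_cross`` and a poor peripheral end
      (``min(r1, r4) < tau_periph``) -> **type 3**;
    * crossing index < ``tau_cross`` with a well-perfused ipsilateral
      periphery (``r1 >= tau_periph``) -> **type 1**;
    * otherwise -> **type 2**.

    The rule is total: every feature vector receives exactly one label.
    """
    if features.crossing_index >= tau_cross and min(features.r1, features.r4) < tau_periph:
        label = 3
    elif features.crossing_index < tau_cross and features.r1 >= tau_periph:
        label = 1
    else:
        label = 2
    return PatternLabel(label=label, features=features,
                        tau_cross=tau_cross, tau_periph=tau_periph)


def classify_map(
    pmap: PerfusionMap,
    zones: ZoneSet,
    geometry: FlapGeometry,
    band_frac: float = DEFAULT_BAND_FRAC,
    tau_cross: float = DEFAULT_TAU_CROSS,
    tau_periph: float = DEFAULT_TAU_PERIPH,
) -> PatternLabel:
    """Convenience: features + classification in one call."""
    feats = extract_pattern_features(pmap, zones, geometry, band_frac=band_frac)
    return classify_pattern(feats, tau_cross=tau_cross, tau_periph=tau_periph)
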