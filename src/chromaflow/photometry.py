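"""Blank-referenced transmittance and Beer-Lambert absorbance.

A colored reaction product attenuates light reaching the camera.  With the
blank frame's channel intensity taken as the incident intensity I0 and the
sample frame's as the transmitted intensity It, the per-channel
transmittance is T = It/I0 and the absorbance A = -log10(T), which at a
fixed optical path length is proportional to analyte concentration.

Because both frames pass through the same phone, LED and reagent batch,
any multiplicative gain (device, illumination) cancels in the ratio — this
is what makes the readout device-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateBlankError, ParameterError
from .imaging import Channel, RawRGB

#: Floor applied to a zero sample channel so absorbance stays finite.
EPSILON = 1e-6


@dataclass(frozen=True)
class NormalizedIntensity:
    """Per-channel transmittance ratios It/I0, each strictly positive."""

    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=np.float64)


@dataclass(frozen=True)
class AbsorbanceReading:
    """Per-channel absorbance (AU) plus the assay's measurement channel."""

    a_r: float
    a_g: float
    a_b: float
    channel: Channel

    @property
    def value(self) -> float:
        """Absorbance on the selected measurement channel."""
        return (self.a_r, self.a_g, self.a_b)[self.channel.index]


def normalize(
    sample: RawRGB,
    blank: RawRGB,
    clip_transmittance: bool = True,
    epsilon: float = EPSILON,
) -> NormalizedIntensity:
    """Component-wise transmittance ``sample / blank``.

    Parameters
    ----------
    clip_transmittance
        When true (default), ratios above 1 — a sample brighter than the
        blank, possible under noise — are clipped to 1 so absorbance stays
        non-negative.  Disable to retain signed deviations (the water
        zero-check needs this).
    epsilon
        A sample channel of exactly 0 is floored to this value (with a
        warning) so the downstream log stays finite.
    """
    s = sample.as_array()
    b = blank.as_array()
    if np.any(b <= 0):
        dead = [("red", "green", "blue")[i] for i in np.flatnonzero(b <= 0)]
        raise DegenerateBlankError(
            f"blank channel(s) {', '.join(dead)} are zero; cannot normalize"
        )
    if np.any(s <= 0):
        warnings.warn(
            "sample channel at 0 floored to epsilon for finite absorbance",
            RuntimeWarning,
            stacklevel=2,
        )
        s = np.maximum(s, epsilon)
    t = s / b
    if clip_transmittance:
        t = np.minimum(t, 1.0)
    return NormalizedIntensity(float(t[0]), float(t[1]), float(t[2]))


def absorbance(t: NormalizedIntensity, channel: Channel) -> AbsorbanceReading:
    """Beer-Lambert absorbance A = -log10(T) per channel."""
    arr = t.as_array()
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ParameterError(
            f"transmittance components must be finite and > 0, got {arr}"
        )
    a = -np.log10(arr)
    return AbsorbanceReading(float(a[0]), float(a[1]), float(a[2]), channel)


def select_channel(assay) -> Channel:
    """Measurement channel configured for an assay.

    Defaults follow complementary-color reasoning: a dye absorbs most
    strongly in the channel complementary to its perceived color (pink-red
    quinoneimine -> green, yellow-orange Jaffe complex -> blue, green BCG
    complex -> red).
    """
    return Channel(assay.channel)
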