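"""Cell color-coding for matrix export.

Potency uses the continuous red (low) -> yellow -> green (high) spectrum;
promiscuity degree uses white (0) -> dark blue (many targets).
Unannotated real cells render gray, virtual cells white/empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

RGB = tuple[int, int, int]

GRAY: RGB = (200, 200, 200)
WHITE: RGB = (255, 255, 255)
_RED: RGB = (255, 0, 0)
_YELLOW: RGB = (255, 255, 0)
_GREEN: RGB = (0, 200, 0)
_DARK_BLUE: RGB = (8, 48, 107)

PER_MATRIX = "per_matrix"
GLOBAL = "global"


@dataclass(frozen=True)
class ColorScale:
    """kind: "potency" (pKi range) or "promiscuity" (target-count range);
    mode records whether the range came from one matrix or the whole
    data set."""

    kind: str
    low: float
    high: float
    mode: str = PER_MATRIX

    def __post_init__(self) -> None:
        if self.kind not in ("potency", "promiscuity"):
            raise ValueError("kind must be 'potency' or 'promiscuity'")
        if not self.low < self.high:
            raise ValueError("scale requires low < high")


def _lerp(a: RGB, b: RGB, t: float) -> RGB:
    return tuple(round(a[i] + (b[i] - a[i]) * t) for i in range(3))  # type: ignore[return-value]


def potency_color(pki: float | None, scale: ColorScale) -> RGB:
    """Piecewise-linear red -> yellow -> green; values clamped to the
    scale range; ``None`` (unannotated) maps to gray."""
    if pki is None:
        return GRAY
    t = (pki - scale.low) / (scale.high - scale.low)
    t = min(1.0, max(0.0, t))
    if t <= 0.5:
        return _lerp(_RED, _YELLOW, t * 2)
    return _lerp(_YELLOW, _GREEN, (t - 0.5) * 2)


def promiscuity_color(degree: int | None, scale: ColorScale) -> RGB:
    """White -> dark blue with the number of targets; ``None`` (virtual)
    maps to white."""
    if degree is None:
        return WHITE
    t = (degree - scale.low) / (scale.high - scale.low)
    return _lerp(WHITE, _DARK_BLUE, min(1.0, max(0.0, t)))


def hex_color(rgb: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def scale_for_values(kind: str, values: Sequence[float],
                     mode: str = PER_MATRIX) -> ColorScale:
    """Scale spanning the observed values (padded when degenerate)."""
    if not values:
        return ColorScale(kind, 0.0, 1.0, mode)
    low, high = min(values), max(values)
    if low == high:
        low, high = low - 0.5, high + 0.5
    return ColorScale(kind, low, high, mode)
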