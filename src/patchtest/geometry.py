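"""Pixel rectangles used for chamber regions of interest.

All rectangles are 0-based, half-open ``(x0, y0, x1, y1)``: the pixel at
``(x1 - 1, y1 - 1)`` is the last one inside, ``(x1, y1)`` is outside.
"""

from __future__ import annotations

from typing import NamedTuple


class Roi(NamedTuple):
    """Axis-aligned half-open pixel rectangle ``(x0, y0, x1, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def is_degenerate(self) -> bool:
        return self.x1 <= self.x0 or self.y1 <= self.y0

    def within(self, height: int, width: int) -> bool:
        """True if the rectangle lies fully inside an ``height x width`` image."""
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= width and self.y1 <= height

    def shifted(self, dx: int = 0, dy: int = 0) -> "Roi":
        return Roi(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def overlaps(self, other: "Roi") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )
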