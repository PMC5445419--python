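"""In-memory container for a single-channel fluorescence image.

The tool operates on 2D maximum-intensity projections.  Pixel (r, c)
covers the unit square centred on the continuous coordinate (row=r,
col=c); all subpixel positions use this pixel-centre convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_SIDE = 16


@dataclass
class FluorescenceImage:
    """A 2D grid of nonnegative intensities with channel provenance.

    Parameters
    ----------
    pixels
        2D float array of intensities; must be finite, at least
        ``MIN_SIDE`` pixels on each side.
    channel
        Free-form channel label (e.g. ``"mRNA"``, ``"protein"``).
    is_max_projection
        Whether the grid is a maximum-intensity projection of a stack.
    pixel_size_um
        Physical pixel pitch, if known.  Purely informational.
    background
        Scalar background that has been subtracted from ``pixels``
        (``None`` if no subtraction was applied).
    """

    pixels: np.ndarray
    channel: str = ""
    is_max_projection: bool = True
    pixel_size_um: float | None = None
    background: float | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE} px, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **overrides) -> "FluorescenceImage":
        """Return a copy with new pixel data, preserving metadata."""
        kw = dict(
            channel=self.channel,
            is_max_projection=self.is_max_projection,
            pixel_size_um=self.pixel_size_um,
            background=self.background,
        )
        kw.update(overrides)
        return FluorescenceImage(pixels=pixels, **kw)
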