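"""Synthetic FISH-like scenes with known ground truth.

Generates two matched channels for an elliptical cell:

* an mRNA channel — a low constant background plus diffraction-limited
  spots rendered as isotropic 2D Gaussians of a common point-spread
  function, placed inside the cell with a tunable posterior enrichment;
* a protein channel — piecewise-uniform intensity over the cell with a
  tunable posterior share of the total signal.

Every downstream stage (spot detection, unit calibration, count
estimation, bisection, polarity statistics) is tested against the
ground truth recorded here: exact spot positions, their
anterior/posterior labels, and the cell/nucleus geometry.

Spot placement under posterior enrichment ``f`` is a two-step process:
each spot independently chooses the posterior half with probability
``f`` (Bernoulli), then lands uniformly within that half of the cell
mask.  This gives exact per-spot ground-truth labels and makes the
posterior count Binomial(n_spots, f).

The PSF is evaluated at pixel centres (not integrated over pixel
area); all quantification stages share the same convention through
:func:`render_spots`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .image import FluorescenceImage

STREAM_POSITIONS = ("beginning", "middle", "end", "single")

# Truncation radius (in sigmas) for rendering a Gaussian spot.  At 6
# sigma the omitted tail carries < 1e-8 of the integrated intensity.
_RENDER_RADIUS_SIGMA = 6.0


def render_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitude: float,
    sigma: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Additively render isotropic Gaussian spots at subpixel positions.

    Each spot contributes ``amplitude * exp(-d^2 / (2 sigma^2))``
    evaluated at pixel centres, truncated beyond 6 sigma.  This is the
    single rendering convention shared by the scene generator and the
    image-reconstruction estimator.
    """
    rows, cols = shape
    img = out if out is not None else np.zeros(shape, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return img
    rad = int(math.ceil(_RENDER_RADIUS_SIGMA * sigma))
    for r0, c0 in positions:
        r_lo = max(0, int(math.floor(r0)) - rad)
        r_hi = min(rows, int(math.ceil(r0)) + rad + 1)
        c_lo = max(0, int(math.floor(c0)) - rad)
        c_hi = min(cols, int(math.ceil(c0)) + rad + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi, dtype=float)[:, None]
        cc = np.arange(c_lo, c_hi, dtype=float)[None, :]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return img


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic cell scene.

    Angles are radians in the (col, row) image plane: the polarity axis
    direction is ``(d_col, d_row) = (cos angle, sin angle)`` and points
    from the cell toward the aggregation centre (the anterior side).
    ``nucleus_offset`` displaces the nucleus from the cell centre along
    this axis (positive = toward the anterior).

    ``enrichment`` is the expected fraction of spots in the posterior
    half; 0.5 means spatially uniform placement.  The noise model is
    optional Poisson shot noise on (background + signal) followed by
    additive Gaussian read noise.
    """

    image_shape: tuple[int, int] = (128, 128)
    cell_axes: tuple[float, float] = (36.0, 20.0)
    cell_center: tuple[float, float] = (64.0, 64.0)
    polarity_axis_angle: float = 0.0
    nucleus_offset: float = 0.0
    n_spots: int = 40
    enrichment: float = 0.5
    unit_amplitude: float = 120.0
    unit_sigma: float = 1.5
    background: float = 10.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    protein_posterior_fraction: float = 0.5
    seed: int = 0
    # -- generator plumbing, not part of the imaging model ------------
    nucleus_radius: float = 5.0
    protein_mean_intensity: float = 50.0
    border_margin_sigma: float = 3.0  # reject spots this close to the border; 0 = off
    min_spot_separation: float = 0.0  # enforce pairwise spot distance; 0 = off
    stream_position: str = "single"

    def __post_init__(self) -> None:
        a, b = self.cell_axes
        if not (a >= b > 0):
            raise ValueError(f"cell_axes must satisfy a >= b > 0, got {self.cell_axes}")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")
        if not 0.0 <= self.protein_posterior_fraction <= 1.0:
            raise ValueError("protein_posterior_fraction must be in [0, 1]")
        if self.unit_sigma <= 0:
            raise ValueError("unit_sigma must be > 0")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read_noise_sd must be >= 0")
        if self.stream_position not in STREAM_POSITIONS:
            raise ValueError(
                f"unknown stream_position {self.stream_position!r}; "
                f"expected one of {STREAM_POSITIONS}"
            )
        rows, cols = self.image_shape
        cr, cc = self.cell_center
        # conservative bound: the rotated ellipse fits inside a disk of radius a
        if cr - a < 0 or cr + a > rows - 1 or cc - a < 0 or cc + a > cols - 1:
            raise ValueError(
                "cell ellipse (semi-major axis {:.1f} at centre {}) exceeds "
                "image bounds {}".format(a, self.cell_center, self.image_shape)
            )

    @property
    def axis_direction(self) -> np.ndarray:
        """Unit anterior direction as (row, col)."""
        return np.array(
            [math.sin(self.polarity_axis_angle), math.cos(self.polarity_axis_angle)]
        )


@dataclass
class SyntheticScene:
    """Ground truth for one rendered cell."""

    params: SceneParams
    spot_positions: np.ndarray  # (n, 2) subpixel (row, col)
    spot_labels: np.ndarray  # (n,) bool, True = posterior
    true_anterior_count: int
    true_posterior_count: int
    cell_polygon: Polygon  # shapely, (x=col, y=row)
    nucleus_centroid: tuple[float, float]  # (row, col)
    aggregation_point: tuple[float, float]  # (row, col)

    def __post_init__(self) -> None:
        assert self.true_anterior_count + self.true_posterior_count == len(
            self.spot_positions
        )


def ellipse_polygon(
    center_rc: tuple[float, float],
    a: float,
    b: float,
    angle: float,
    n_vertices: int = 128,
) -> Polygon:
    """Polygonal approximation of a rotated ellipse (shapely x=col, y=row)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    # parametric ellipse in the axis frame, then rotate into image frame
    u = a * np.cos(t)
    v = b * np.sin(t)
    d_row, d_col = math.sin(angle), math.cos(angle)
    rows = center_rc[0] + u * d_row + v * d_col
    cols = center_rc[1] + u * d_col - v * d_row
    return Polygon(np.column_stack([cols, rows]))


def _sample_spots(params: SceneParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample spot positions and posterior labels."""
    a, b = params.cell_axes
    cr, cc = params.cell_center
    angle = params.polarity_axis_angle
    d = params.axis_direction
    nuc = np.array(params.cell_center) + params.nucleus_offset * d
    margin = params.border_margin_sigma * params.unit_sigma
    rows, cols = params.image_shape
    sep2 = params.min_spot_separation**2

    labels = rng.random(params.n_spots) < params.enrichment  # True = posterior
    positions = np.empty((params.n_spots, 0 + 2))
    placed: list[np.ndarray] = []
    d_row, d_col = math.sin(angle), math.cos(angle)
    for i, is_post in enumerate(labels):
        for _attempt in range(100_000):
            # uniform in the ellipse via uniform disk mapped by the axes
            r = math.sqrt(rng.random())
            phi = rng.random() * 2.0 * math.pi
            u, v = a * r * math.cos(phi), b * r * math.sin(phi)
            p = np.array([cr + u * d_row + v * d_col, cc + u * d_col - v * d_row])
            side = float(np.dot(p - nuc, d))
            if (side < 0) != bool(is_post):
                continue
            if margin > 0 and not (
                margin <= p[0] <= rows - 1 - margin and margin <= p[1] <= cols - 1 - margin
            ):
                continue
            if sep2 > 0 and any(np.sum((p - q) ** 2) < sep2 for q in placed):
                continue
            placed.append(p)
            break
        else:
            raise RuntimeError(
                "could not place spot %d; constraints too tight "
                "(min_spot_separation=%.2f, border margin=%.2f)"
                % (i, params.min_spot_separation, margin)
            )
    positions = np.array(placed).reshape(params.n_spots, 2)
    return positions, labels


def render_scene(
    params: SceneParams,
) -> tuple[SyntheticScene, FluorescenceImage, FluorescenceImage]:
    """Render one synthetic cell: ground truth plus mRNA and protein channels.

    Fully reproducible from ``params.seed``.  Returns
    ``(scene, mrna_image, protein_image)``.
    """
    rng = np.random.default_rng(params.seed)
    a, b = params.cell_axes
    d = params.axis_direction
    nuc = np.array(params.cell_center) + params.nucleus_offset * d
    agg = np.array(params.cell_center) + 2.0 * a * d  # anterior side marker

    positions, labels = _sample_spots(params, rng)

    mrna = np.full(params.image_shape, float(params.background))
    render_spots(params.image_shape, positions, params.unit_amplitude, params.unit_sigma, out=mrna)

    # protein channel: piecewise-uniform over the cell, posterior share fixed
    rr, cc_idx = np.indices(params.image_shape)
    cell_poly = ellipse_polygon(params.cell_center, a, b, params.polarity_axis_angle)
    in_cell = shapely.contains_xy(cell_poly, cc_idx.ravel(), rr.ravel()).reshape(params.image_shape)
    side = (rr - nuc[0]) * d[0] + (cc_idx - nuc[1]) * d[1]
    post_mask = in_cell & (side < 0)
    ant_mask = in_cell & (side >= 0)  # boundary ties are anterior throughout
    n_post, n_ant = int(post_mask.sum()), int(ant_mask.sum())
    protein = np.full(params.image_shape, float(params.background))
    total = params.protein_mean_intensity * (n_post + n_ant)
    p = params.protein_posterior_fraction
    if n_post:
        protein[post_mask] += total * p / n_post
    if n_ant:
        protein[ant_mask] += total * (1.0 - p) / n_ant

    if params.poisson_noise:
        mrna = rng.poisson(mrna).astype(float)
        protein = rng.poisson(protein).astype(float)
    if params.read_noise_sd > 0:
        mrna = mrna + rng.normal(0.0, params.read_noise_sd, params.image_shape)
        protein = protein + rng.normal(0.0, params.read_noise_sd, params.image_shape)

    scene = SyntheticScene(
        params=params,
        spot_positions=positions,
        spot_labels=labels,
        true_anterior_count=int((~labels).sum()),
        true_posterior_count=int(labels.sum()),
        cell_polygon=cell_poly,
        nucleus_centroid=(float(nuc[0]), float(nuc[1])),
        aggregation_point=(float(agg[0]), float(agg[1])),
    )
    mrna_img = FluorescenceImage(mrna, channel="mRNA")
    protein_img = FluorescenceImage(protein, channel="protein")
    return scene, mrna_img, protein_img


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (each < 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


def make_stream_cohort(
    n_cells: int,
    position_labels: Sequence[str],
    enrichment_by_position: dict[str, float],
    base_params: SceneParams,
    protein_fraction_by_position: dict[str, float] | None = None,
) -> list[tuple[SyntheticScene, FluorescenceImage, FluorescenceImage]]:
    """Generate a cohort of cells placed along a chemotactic stream.

    ``position_labels`` is assigned cyclically across the ``n_cells``
    cells; each cell's mRNA enrichment comes from
    ``enrichment_by_position``.  If ``protein_fraction_by_position``
    is given, the protein channel's posterior fraction also varies by
    position (a co-polarizing protein); otherwise it stays at the base
    value (a uniformly distributed control).  Per-cell seeds are
    derived deterministically from ``base_params.seed`` so the cohort
    is reproducible as a whole.
    """
    if not position_labels:
        raise ValueError("position_labels must be nonempty")
    for lab in position_labels:
        if lab not in STREAM_POSITIONS:
            raise ValueError(f"unknown stream position label {lab!r}")
        if lab not in enrichment_by_position:
            raise ValueError(f"no enrichment given for position {lab!r}")
        if protein_fraction_by_position is not None and lab not in protein_fraction_by_position:
            raise ValueError(f"no protein fraction given for position {lab!r}")
    seeds = derive_seeds(base_params.seed, n_cells)
    out = []
    for i in range(n_cells):
        lab = position_labels[i % len(position_labels)]
        p = replace(
            base_params,
            seed=seeds[i],
            enrichment=float(enrichment_by_position[lab]),
            stream_position=lab,
            protein_posterior_fraction=float(protein_fraction_by_position[lab])
            if protein_fraction_by_position is not None
            else base_params.protein_posterior_fraction,
        )
        out.append(render_scene(p))
    return out
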