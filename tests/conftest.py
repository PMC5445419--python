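"""Shared fixtures: small synthetic scenes with exact ground truth."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fishpol as fp
from fishpol.calibration import subtract_background

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# generator settings used as the clean oracle regime: no noise, spots
# kept 6 sigma apart so every photometric identity is exact
SPARSE_NOISE_FREE = fp.SceneParams(
    n_spots=12,
    seed=11,
    poisson_noise=False,
    read_noise_sd=0.0,
    min_spot_separation=9.0,  # = 6 x unit_sigma
)

TRUE_UNIT = fp.UnitModel(
    amplitude=SPARSE_NOISE_FREE.unit_amplitude, sigma=SPARSE_NOISE_FREE.unit_sigma
)


@pytest.fixture(scope="session")
def sparse_scene():
    """One noise-free scene with 12 well-separated spots."""
    return fp.render_scene(SPARSE_NOISE_FREE)


@pytest.fixture(scope="session")
def sparse_cohort():
    """Four noise-free well-separated scenes (for pooled calibration)."""
    return fp.make_stream_cohort(4, ["single"], {"single": 0.5}, SPARSE_NOISE_FREE)


@pytest.fixture(scope="session")
def calibrated_unit(sparse_cohort):
    unit, _ = fp.calibrate_unit(
        [m for _, m, _ in sparse_cohort],
        [s.cell_polygon for s, _, _ in sparse_cohort],
    )
    return unit


@pytest.fixture(scope="session")
def noisy_cohort():
    """Six scenes under the default (Poisson + read) noise model."""
    return fp.make_stream_cohort(
        6, ["single"], {"single": 0.5}, fp.SceneParams(n_spots=40, seed=7)
    )


def subtracted(scene, image):
    return subtract_background(image, scene.cell_polygon)


def single_spot_image(
    row: float, col: float, amplitude=100.0, sigma=1.5, shape=(48, 48), background=0.0
):
    """One rendered Gaussian on a constant background (no cell geometry)."""
    px = np.full(shape, float(background))
    fp.render_spots(shape, np.array([[row, col]]), amplitude, sigma, out=px)
    return fp.FluorescenceImage(px, channel="mRNA")


# base conditions for cohort-level statistical studies: a realistically
# noisy 40-spot cell on a small frame, geometry shared across the cohort.
# The polarity axis is oblique to the pixel grid — the generic case; an
# exactly grid-aligned cut is degenerate (the bisecting line then runs
# through a whole column of pixel centres and the tie-break rule hands
# that column to one half)
COHORT_BASE = fp.SceneParams(
    image_shape=(64, 64),
    cell_axes=(18.0, 11.0),
    cell_center=(32.0, 32.0),
    polarity_axis_angle=0.3,
    n_spots=40,
    seed=0,
)


def cohort_records(base, groups, n_per_group, rep_seed, unit=TRUE_UNIT):
    """Linear-count CellRecords for a stream cohort sharing one geometry.

    ``groups`` maps stream position -> (mrna posterior fraction,
    protein posterior fraction).  All cells reuse the base cell
    outline, so the bisection masks are computed once; only spots and
    noise differ between cells.
    """
    from fishpol.geometry import roi_pair_masks
    from fishpol.stats import CellRecord

    scene0, _, _ = fp.render_scene(replace(base, seed=rep_seed))
    pair = fp.bisect_cell(
        scene0.cell_polygon, scene0.nucleus_centroid, scene0.aggregation_point
    )
    ant_mask, post_mask = roi_pair_masks(base.image_shape, pair)
    seeds = fp.derive_seeds(rep_seed, n_per_group * len(groups))
    records, i = [], 0
    for pos, (f_mrna, f_prot) in groups.items():
        for _ in range(n_per_group):
            sc, mrna, prot = fp.render_scene(
                replace(
                    base,
                    seed=seeds[i],
                    enrichment=f_mrna,
                    protein_posterior_fraction=f_prot,
                    stream_position=pos,
                )
            )
            msub = subtract_background(mrna, sc.cell_polygon)
            psub = subtract_background(prot, sc.cell_polygon)
            pa = float(psub.pixels[ant_mask].sum())
            pp = float(psub.pixels[post_mask].sum())
            records.append(
                CellRecord(
                    cell_id=f"{pos}_{i}",
                    stream_position=pos,
                    anterior_count=float(msub.pixels[ant_mask].sum())
                    / unit.integrated_intensity,
                    posterior_count=float(msub.pixels[post_mask].sum())
                    / unit.integrated_intensity,
                    protein_posterior_fraction=pp / (pa + pp),
                )
            )
            i += 1
    return records
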