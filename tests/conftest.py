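import numpy as np
import pytest

import condquant as cq


@pytest.fixture(scope="session")
def rod_study():
    """300 synthetic single rods with 0-3 polar foci, analyzed end to end.

    Shared by the foci-count, distribution and assignment tests so the
    (seconds-scale) render+analyze cost is paid once.
    """
    specs = []
    results = []
    for seed in (101, 102, 103):
        fs = cq.FieldSpec(1024, 1024, seed=seed, bg_sd=5.0)
        cells = cq.sample_rod_cells(fs, 100)
        images, manifest = cq.render_cell_field(fs, cells)
        result = cq.analyze_cell_field(images[0])
        specs.append((fs, cells))
        results.append(result)
    return specs, results


def match_cells(cells_true, rods_detected, max_dist_um=0.5):
    """Pair true cells with detected rods by centroid distance."""
    from condquant.validation import match_by_centroid

    truth = [c.center_um for c in cells_true]
    det = [c.centroid_um for c in rods_detected]
    m = match_by_centroid(truth, det, max_dist_um)
    return [(cells_true[i], rods_detected[j]) for i, j in m.pairs]


@pytest.fixture(scope="session")
def rod_study_pairs(rod_study):
    specs, results = rod_study
    pairs = []
    for (fs, cells), result in zip(specs, results):
        rods = [c for c in result.cells if c.is_single_rod]
        pairs.extend(match_cells(cells, rods))
    return pairs


@pytest.fixture
def small_droplet_field():
    fs = cq.FieldSpec(512, 512, seed=1, bg_sd=10.0)
    drops = cq.sample_droplets(fs, 15, partition_ratios=(2.0,), diameter_range=(0.8, 2.0))
    image, manifest = cq.render_droplet_field(fs, drops)
    return fs, drops, image, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
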