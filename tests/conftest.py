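import math

import pytest

from xylemtrace import classification as cls
from xylemtrace import segmentation as seg
from xylemtrace import synthetic_data as sd


def mini_config(segment_type: str, seed: int, **overrides) -> sd.GeneratorConfig:
    """A scaled-down segment (2 bundles, ~25 vessels) that renders quickly."""
    defaults = dict(
        seed=seed,
        n_bundles=2,
        px_count_mean=14.0,
        mx_count_mean=9.0,
        ring_radius_um=80.0,
        image_shape=(2300, 2300),
    )
    defaults.update(overrides)
    return sd.default_config(segment_type, **defaults)


def match_to_truth(records, truth):
    """Pair each measured record with the nearest ground-truth vessel."""
    pairs = []
    for r in records:
        v = min(truth, key=lambda v: math.hypot(v.center[0] - r.centroid[0],
                                                v.center[1] - r.centroid[1]))
        pairs.append((r, v))
    return pairs


@pytest.fixture(scope="session")
def noisefree_segment():
    """Rendered noise-free apical mini segment with its truth."""
    cfg = mini_config("apical", seed=5, noise_sd=0.0)
    truth = sd.build_ground_truth(cfg)
    pair = sd.render_pair(truth, cfg)
    return cfg, truth, pair


@pytest.fixture(scope="session")
def noisy_segment():
    """Rendered apical mini segment at the default noise level."""
    cfg = mini_config("apical", seed=7)
    truth = sd.build_ground_truth(cfg)
    pair = sd.render_pair(truth, cfg)
    return cfg, truth, pair


@pytest.fixture(scope="session")
def noisefree_records(noisefree_segment):
    cfg, truth, pair = noisefree_segment
    records = seg.measure_vessels(pair)
    classified = cls.classify_all(records, image_center_um=pair.center_um)
    return cfg, truth, pair, classified
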