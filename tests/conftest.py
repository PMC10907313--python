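import numpy as np
import pytest

import memrecruit as mr


@pytest.fixture(scope="session")
def noiseless_field():
    """Three well-separated vesicles, no noise, two planted puncta per vesicle."""
    cfg = mr.ImagingSimConfig(image_shape=(300, 300), n_guvs=3, puncta_per_guv=2,
                              fixed_puncta_count=True, seed=11)
    return mr.generate_guv_image(cfg)


@pytest.fixture(scope="session")
def detector():
    return mr.DetectorParams(min_radius=10, max_radius=40)


def match_detections(detections, truth):
    """Greedy nearest-centre matching of detections to planted vesicles
    (within half the planted radius)."""
    used = set()
    pairs = []
    for g in truth.guvs:
        best = None
        for i, d in enumerate(detections):
            if i in used:
                continue
            dist = float(np.hypot(d.center[0] - g.center[0], d.center[1] - g.center[1]))
            if dist < g.radius / 2 and (best is None or dist < best[0]):
                best = (dist, i)
        if best is not None:
            used.add(best[1])
            pairs.append((g, detections[best[1]], best[0]))
    return pairs
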