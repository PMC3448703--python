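import numpy as np
import pytest

from fociquant.focus_quant import segment_nuclei
from fociquant.image_model import ImageSimParams, generate_image


def match_planted_counts(img, truth, records, seg_cfg=None):
    """Pair each QC-passing nucleus with its planted focus count.

    Segmented nuclei are matched to ground-truth nuclei by nearest centroid;
    returns a list of (planted_count, pipeline_count) tuples.
    """
    nuclei = segment_nuclei(img.dapi, seg_cfg)
    planted = truth.foci_counts()
    by_label = {r.nucleus_label: r.foci_count for r in records}
    pairs = []
    for n in (x for x in nuclei if x.qc_pass):
        cen = n.coords.mean(axis=0)
        dists = [np.hypot(cen[0] - t.center_rc[0], cen[1] - t.center_rc[1])
                 for t in truth.nuclei]
        pairs.append((int(planted[int(np.argmin(dists))]),
                      int(by_label[n.label])))
    return pairs


@pytest.fixture(scope="session")
def noiseless_batch():
    """Seven clean images (no noise, no deformed nuclei), 210 nuclei total."""
    out = []
    for s in range(7):
        params = ImageSimParams(n_nuclei=30, image_width_px=640,
                                image_height_px=640, nucleus_radius_px=18,
                                nucleus_radius_spread=0.10,
                                deformed_fraction=0.0, noise_sd=0.0, seed=s)
        out.append(generate_image(params))
    return out
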