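import numpy as np
import pytest

import hcsprotect as h


@pytest.fixture(scope="session")
def small_layouts():
    """Three replicates of a 40-miRNA screen (one plate per replicate)."""
    return h.generate_layout(40, 3, seed=11)


@pytest.fixture(scope="session")
def small_ids(small_layouts):
    return sorted({m for lay in small_layouts for m in lay.mirna_map.values()})


@pytest.fixture(scope="session")
def neutral_truth(small_ids):
    return h.make_ground_truth(small_ids, seed=5)


@pytest.fixture(scope="session")
def neutral_well_table(small_layouts, neutral_truth):
    return h.simulate_well_table(small_layouts, neutral_truth, seed=7)


@pytest.fixture(scope="session")
def imaging_params():
    return h.ImagingParams()


@pytest.fixture(scope="session")
def dark_reference_records(neutral_truth, imaging_params):
    """Segmented nuclei from three simulated dark-control wells."""
    records = []
    for s in (301, 302, 303):
        well = h.render_well_image(None, False, neutral_truth, imaging_params,
                                   seed=s)
        records.extend(h.segment_nuclei(well.image))
    return records


def match_centroids(planted, detected, tol=3.0):
    """Greedy nearest matching of planted nucleus centers to detections.

    Returns (n_matched, matched_pairs) where pairs are (planted_idx,
    detected_idx).  Used as the segmentation-accuracy oracle.
    """
    from scipy.spatial.distance import cdist

    if len(planted) == 0 or len(detected) == 0:
        return 0, []
    d = cdist(np.asarray(planted), np.asarray(detected))
    pairs = []
    used_p, used_d = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for pi, di in order:
        if d[pi, di] > tol:
            break
        if pi in used_p or di in used_d:
            continue
        pairs.append((int(pi), int(di)))
        used_p.add(pi)
        used_d.add(di)
    return len(pairs), pairs
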