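import numpy as np
import pytest

import mplexquant as mq


@pytest.fixture(scope="session")
def small_phantom():
    """512² phantom with two islets, noise and background on."""
    cfg = mq.TissuePhantomConfig(
        image_size_px=(512, 512),
        n_cells=150,
        seed=5,
        islet_specs=[((150.0, 150.0), 45.0), ((360.0, 360.0), 55.0)],
    )
    return mq.generate_tissue(cfg)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same geometry with zero noise/background and zero intensity spread."""
    cfg = mq.TissuePhantomConfig(
        image_size_px=(512, 512),
        n_cells=150,
        seed=5,
        islet_specs=[((150.0, 150.0), 45.0), ((360.0, 360.0), 55.0)],
    ).noiseless()
    return mq.generate_tissue(cfg)


def random_nucleus_labels(rng, shape=(128, 128), n_nuclei=12, r_lo=3, r_hi=7):
    """Disk nuclei at random non-overlapping positions, labels 1..N."""
    from skimage.draw import disk

    labels = np.zeros(shape, dtype=np.int32)
    placed = []
    lab = 0
    tries = 0
    while lab < n_nuclei and tries < 2000:
        tries += 1
        rad = int(rng.integers(r_lo, r_hi + 1))
        r = int(rng.integers(rad + 1, shape[0] - rad - 1))
        c = int(rng.integers(rad + 1, shape[1] - rad - 1))
        if any((r - pr) ** 2 + (c - pc) ** 2 <= (rad + prad + 1) ** 2
               for pr, pc, prad in placed):
            continue
        lab += 1
        rr, cc = disk((r, c), rad, shape=shape)
        labels[rr, cc] = lab
        placed.append((r, c, rad))
    return labels


def brute_force_tessellation(labels, expansion_px):
    """Independent nearest-nucleus-pixel assignment via KD-trees.

    For every pixel, the squared Euclidean distance to each nucleus' pixel
    set is computed exactly; the closest nucleus within the expansion
    radius wins, ties to the smaller label.
    """
    from scipy.spatial import cKDTree

    h, w = labels.shape
    pix = np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"),
                   axis=-1).reshape(-1, 2)
    best_d2 = np.full(len(pix), np.inf)
    best_l = np.zeros(len(pix), dtype=np.int32)
    for lab in np.unique(labels[labels > 0]):
        pts = np.argwhere(labels == lab)
        d, _ = cKDTree(pts).query(pix)
        d2 = np.round(d * d).astype(np.int64)  # distances are sqrt of ints
        better = d2 < best_d2
        best_d2 = np.where(better, d2, best_d2)
        best_l = np.where(better, lab, best_l)
    best_l[best_d2 > expansion_px**2] = 0
    return best_l.reshape(h, w)
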