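import numpy as np
import pytest

from fibroquant import (
    SlideImage,
    SyntheticSpec,
    generate_slide,
    segment_collagen,
)


@pytest.fixture(scope="session")
def small_slide():
    """One noiseless 256x256 synthetic slide at a mid-range fibrosis level."""
    return generate_slide(
        SyntheticSpec(
            width_px=256, height_px=256, target_collagen_fraction=0.06, disorder=0.3, seed=11
        )
    )


@pytest.fixture(scope="session")
def small_seg(small_slide):
    return segment_collagen(SlideImage(pixels=small_slide.image, slide_id="small"))


def naive_local_entropy(sr_od, tissue, window, bins, log_base_e=True):
    """Brute-force sliding-window entropy oracle: per-pixel histogram of the
    quantized OD over tissue pixels in the window, O(N * w^2)."""
    t_od = sr_od[tissue]
    lo, hi = float(t_od.min()), float(t_od.max())
    if hi <= lo:
        q = np.zeros_like(sr_od, dtype=np.int64)
    else:
        q = np.clip(np.floor((sr_od - lo) / (hi - lo) * bins).astype(np.int64), 0, bins - 1)
    h, w = sr_od.shape
    r = window // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            y0, y1 = max(i - r, 0), min(i + r + 1, h)
            x0, x1 = max(j - r, 0), min(j + r + 1, w)
            patch_q = q[y0:y1, x0:x1]
            patch_t = tissue[y0:y1, x0:x1]
            vals = patch_q[patch_t]
            if vals.size == 0:
                continue
            counts = np.bincount(vals, minlength=bins)
            p = counts / vals.size
            ent = 0.0
            for b in range(bins):
                if p[b] > 0:
                    ent += -p[b] * np.log(p[b])
            if not log_base_e:
                ent /= np.log(2.0)
            out[i, j] = ent
    return out


def naive_fleiss_kappa(table):
    """Direct implementation of the Fleiss kappa formula on an
    items x categories count table."""
    table = np.asarray(table, dtype=float)
    n_items, _ = table.shape
    n_raters = table[0].sum()
    p_cat = table.sum(axis=0) / (n_items * n_raters)
    p_item = ((table**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_item.mean()
    pe = (p_cat**2).sum()
    return (p_bar - pe) / (1.0 - pe)
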