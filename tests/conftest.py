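import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_partition(sinus, exclusions, dilation_um, pixel_size):
    """All-pairs Euclidean distance oracle for SPA/SDA segmentation.

    Computes, for every canvas pixel, the minimum distance to every sinus
    pixel explicitly (no distance transform), then thresholds.
    """
    rows, cols = sinus.shape
    sinus_pts = np.argwhere(sinus)  # (M, 2)
    rr, cc = np.mgrid[0:rows, 0:cols]
    pixels = np.column_stack([rr.ravel(), cc.ravel()])  # (N, 2)
    d2 = (
        (pixels[:, None, 0] - sinus_pts[None, :, 0]) ** 2
        + (pixels[:, None, 1] - sinus_pts[None, :, 1]) ** 2
    ).min(axis=1)
    spa = (np.sqrt(d2).reshape(rows, cols) * pixel_size) <= dilation_um
    sda = ~spa
    spa = spa & ~exclusions
    sda = sda & ~exclusions
    return spa, sda


def brute_force_coverage(signal, spa, sda, exclusions):
    """Pixel-count oracle for per-region coverage statistics."""
    sig = signal & ~exclusions
    total = (sig & (spa | sda)).sum()
    out = {}
    for name, region in (("SPA", spa), ("SDA", sda)):
        s = int((sig & region).sum())
        area = int(region.sum())
        out[name] = {
            "signal_px": s,
            "area_px": area,
            "coverage_pct": 100.0 * s / area if area else np.nan,
            "signal_fraction_pct": 100.0 * s / total if total else np.nan,
        }
    return out


def brute_force_sharing(counts_df, founder_like=False):
    """Enumeration oracle over all (allele, organ) incidences.

    Returns dicts of multi-organ, pairwise, and exclusive sharing computed
    by explicit loops over rows, independent of the vectorized path.
    """
    organs = list(counts_df.columns)
    multi, pair, excl = {}, {}, {}
    for a in organs:
        tot = counts_df[a].sum()
        num = 0
        for _, row in counts_df.iterrows():
            if row[a] > 0 and any(row[o] > 0 for o in organs if o != a):
                num += row[a]
        multi[a] = 100.0 * num / tot if tot else np.nan
        for b in organs:
            if b == a:
                continue
            pnum = enum = 0
            for _, row in counts_df.iterrows():
                if row[a] > 0 and row[b] > 0:
                    pnum += row[a]
                    if not any(row[o] > 0 for o in organs if o not in (a, b)):
                        enum += row[a]
            pair[(a, b)] = 100.0 * pnum / tot if tot else np.nan
            excl[(a, b)] = 100.0 * enum / tot if tot else np.nan
    return multi, pair, excl
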