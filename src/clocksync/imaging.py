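"""Fixed-cell nucleocytoplasmic quantification.

Per cell, the nucleus is segmented from the nuclear-stain channel, the
cytoplasmic compartment is approximated by a ring obtained by dilating the
nucleus boundary outward by a fixed number of pixels (3 by default), and the
nucleus-to-cytoplasm (N/C) ratio of each protein channel is the mean nuclear
intensity divided by the mean ring intensity.

Coordinates are pixel-centered, 0-based, (row, col).  Cells whose ring is
clipped by the image border or fully crowded out are retained in the output
table with an explicit quality flag instead of being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels, watershed

from .errors import ClockSyncError

__all__ = [
    "MultiChannelImage",
    "segment_nuclei",
    "cytoplasm_ring",
    "measure_nc",
    "nc_summary",
    "DEFAULT_DILATION_PX",
]

DEFAULT_DILATION_PX = 3


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels sharing one shape; ``nuclear_stain`` required."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "nuclear_stain" not in self.channels:
            raise ClockSyncError("MultiChannelImage requires a 'nuclear_stain' channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ClockSyncError(f"channel shapes differ: {shapes}")
        for c, a in self.channels.items():
            if a.ndim != 2:
                raise ClockSyncError(f"channel {c!r} is not 2-D")
            if not np.isfinite(a).all() or (a < 0).any():
                raise ClockSyncError(f"channel {c!r} has non-finite or negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise ClockSyncError(f"channel {channel!r} not present") from None

    @classmethod
    def from_tiff(cls, path, channel_names: list[str]) -> "MultiChannelImage":
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if len(channel_names) != stack.shape[0]:
            raise ClockSyncError(
                f"{len(channel_names)} channel names for {stack.shape[0]} pages"
            )
        return cls({n: stack[i].astype(float) for i, n in enumerate(channel_names)})


def segment_nuclei(
    image: MultiChannelImage,
    method: str = "otsu",
    min_area: int = 50,
    sigma: float = 1.0,
    threshold: float | None = None,
    split_touching: bool = False,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Label nuclei in the nuclear-stain channel.

    ``method`` is ``"otsu"`` (Otsu threshold on a Gaussian-smoothed channel),
    ``"fixed"`` (user-supplied ``threshold`` on the raw channel) or
    ``"external"`` (pass a pre-computed boolean/label ``mask`` through).
    Components smaller than ``min_area`` pixels are removed.  With
    ``split_touching`` a distance-transform watershed separates merged
    nuclei.  Deterministic for fixed input and settings; an image with no
    detectable objects yields an all-zero mask (not an error).
    """
    nuc = image["nuclear_stain"].astype(float)
    if method == "otsu":
        sm = gaussian(nuc, sigma=sigma, preserve_range=True) if sigma > 0 else nuc
        if np.ptp(sm) == 0:
            return np.zeros(nuc.shape, dtype=np.int32)
        binary = sm > threshold_otsu(sm)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        binary = nuc > threshold
    elif method == "external":
        if mask is None:
            raise ValueError("method='external' requires a mask")
        binary = np.asarray(mask) > 0
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    labels = cc_label(binary).astype(np.int32)
    if split_touching and labels.max() > 0:
        dist = ndi.distance_transform_edt(binary)
        smooth = ndi.gaussian_filter(dist, sigma=2.0)
        peaks = (smooth == ndi.maximum_filter(smooth, size=7)) & binary
        markers = cc_label(peaks)
        labels = watershed(-dist, markers, mask=binary).astype(np.int32)

    # area filter, then relabel compactly so ids are 1..n
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def cytoplasm_ring(nuclei: np.ndarray, dilation_px: int = DEFAULT_DILATION_PX) -> np.ndarray:
    """Cytoplasmic ring mask: each nucleus dilated outward, minus all nuclei.

    Pixels reachable by two cells' rings go to the nearer nucleus (exact
    Euclidean distance; ties broken deterministically by the underlying
    distance transform).  Ring labels match nucleus labels.
    """
    if dilation_px < 1:
        raise ValueError("dilation_px must be >= 1")
    expanded = expand_labels(nuclei, distance=dilation_px)
    ring = expanded.copy()
    ring[nuclei > 0] = 0
    return ring.astype(np.int32)


def _region_means(channel: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    sums = ndi.sum_labels(channel, labels, ids)
    counts = ndi.sum_labels(np.ones_like(channel), labels, ids)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def measure_nc(
    image: MultiChannelImage,
    nuclei: np.ndarray,
    rings: np.ndarray,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell, per-channel nuclear and ring means and their N/C ratio.

    Returns a tidy table (cell_id, channel, nuc_mean, cyto_mean, nc_ratio,
    qc_flags).  ``qc_flags`` is empty for clean cells; flagged cells
    (``no_cytoplasm``, ``edge``, ``zero_cyto``) keep their row with
    ``nc_ratio`` NaN where undefined.  Rows with any flag should be excluded
    from downstream statistics.
    """
    if channels is None:
        channels = [c for c in image.channels if c != "nuclear_stain"]
    for c in channels:
        image[c]  # raises with the channel name if missing

    ids = np.unique(nuclei[nuclei > 0])
    h, w = nuclei.shape
    border = np.zeros((h, w), bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True

    ring_areas = ndi.sum_labels(np.ones(rings.shape), rings, ids) if len(ids) else []
    rows = []
    for k, cid in enumerate(ids):
        flags = []
        if ring_areas[k] == 0:
            flags.append("no_cytoplasm")
        if (border & ((nuclei == cid) | (rings == cid))).any():
            flags.append("edge")
        for c in channels:
            ch = image[c].astype(float)
            nuc_mean = float(ch[nuclei == cid].mean())
            cyto_px = ch[rings == cid]
            cyto_mean = float(cyto_px.mean()) if cyto_px.size else np.nan
            cell_flags = list(flags)
            if cyto_px.size and cyto_mean == 0:
                cell_flags.append("zero_cyto")
            ratio = (
                nuc_mean / cyto_mean
                if cyto_px.size and cyto_mean > 0
                else np.nan
            )
            rows.append({
                "cell_id": int(cid), "channel": c, "nuc_mean": nuc_mean,
                "cyto_mean": cyto_mean, "nc_ratio": ratio,
                "qc_flags": ";".join(cell_flags),
            })
    return pd.DataFrame(rows, columns=["cell_id", "channel", "nuc_mean",
                                       "cyto_mean", "nc_ratio", "qc_flags"])


def nc_summary(
    table: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    bins: int = 20,
) -> dict:
    """Histograms of per-cell N/C ratios and their Pearson correlation.

    Only cells with a clean (unflagged) finite ratio in both channels enter
    the correlation; fewer than 3 shared cells is an error.
    """
    from scipy.stats import pearsonr

    clean = table[(table["qc_flags"] == "") & np.isfinite(table["nc_ratio"])]
    a = clean[clean["channel"] == channel_a].set_index("cell_id")["nc_ratio"]
    b = clean[clean["channel"] == channel_b].set_index("cell_id")["nc_ratio"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ClockSyncError(
            f"need >= 3 shared cells for correlation, have {len(shared)}"
        )
    av, bv = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        r, p = (1.0 if np.array_equal(av, bv) else np.nan), np.nan
    else:
        r, p = pearsonr(av, bv)
    hists = {
        c: np.histogram(clean[clean["channel"] == c]["nc_ratio"], bins=bins)
        for c in (channel_a, channel_b)
    }
    return {"r": float(r), "p": float(p) if np.isfinite(p) else np.nan,
            "n_cells": int(len(shared)), "histograms": hists}
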