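"""Nuclear/cytoplasmic quantification on synthetic fixed-cell images."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from clocksync.errors import ClockSyncError
from clocksync.imaging import (
    MultiChannelImage,
    cytoplasm_ring,
    measure_nc,
    nc_summary,
    segment_nuclei,
)
from clocksync.synth import ImagingScenario, gen_fixed_cell_image


@pytest.fixture(scope="module")
def clean_scene():
    img, truth = gen_fixed_cell_image(ImagingScenario(n_cells=10, noise_sd=0.0, seed=7))
    return img, truth


def _match_measured_to_truth(labels, table, truth, channel):
    """Pair measured cells with truth rows via nearest centers."""
    ids = np.unique(labels[labels > 0])
    cents = np.asarray(ndi.center_of_mass(np.ones_like(labels), labels, ids))
    tc = truth[["row", "col"]].to_numpy()
    pairs = []
    for cid, cent in zip(ids, cents):
        k = np.argmin(np.linalg.norm(tc - cent, axis=1))
        meas = table[(table.cell_id == cid) & (table.channel == channel)]
        pairs.append((truth[f"true_nc_ratio_{channel}"].iloc[k],
                      meas["nc_ratio"].iloc[0]))
    return pairs


class TestSegmentation:
    def test_finds_each_disk(self, clean_scene):
        img, truth = clean_scene
        labels = segment_nuclei(img)
        assert labels.max() == len(truth)

    def test_blank_image_yields_empty_mask(self):
        img = MultiChannelImage({"nuclear_stain": np.zeros((64, 64))})
        assert segment_nuclei(img).max() == 0

    def test_min_area_filters_specks(self):
        arr = np.zeros((64, 64))
        arr[10:13, 10:13] = 100.0     # 9-px object
        arr[30:45, 30:45] = 100.0     # 225-px object
        img = MultiChannelImage({"nuclear_stain": arr})
        labels = segment_nuclei(img, min_area=50, sigma=0)
        assert labels.max() == 1
        labels_all = segment_nuclei(img, min_area=5, sigma=0)
        assert labels_all.max() == 2

    def test_deterministic(self, clean_scene):
        img, _ = clean_scene
        a = segment_nuclei(img)
        b = segment_nuclei(img)
        assert np.array_equal(a, b)


class TestRing:
    def test_ring_disjoint_from_all_nuclei(self, clean_scene):
        img, _ = clean_scene
        labels = segment_nuclei(img)
        rings = cytoplasm_ring(labels, dilation_px=3)
        assert not ((labels > 0) & (rings > 0)).any()
        assert (rings > 0).sum() > 0

    def test_contested_pixels_assigned_once(self):
        labels = np.zeros((40, 40), np.int32)
        labels[18:23, 8:13] = 1
        labels[18:23, 14:19] = 2     # one-pixel gap between nuclei
        rings = cytoplasm_ring(labels, dilation_px=3)
        # partition: every ring pixel belongs to exactly one cell by construction
        assert set(np.unique(rings)) <= {0, 1, 2}
        assert (rings == 1).any() and (rings == 2).any()
        assert not ((labels > 0) & (rings > 0)).any()

    def test_ring_width_follows_dilation(self):
        labels = np.zeros((41, 41), np.int32)
        rr, cc = np.ogrid[:41, :41]
        labels[(rr - 20) ** 2 + (cc - 20) ** 2 <= 64] = 1
        r3 = (cytoplasm_ring(labels, 3) > 0).sum()
        r5 = (cytoplasm_ring(labels, 5) > 0).sum()
        assert r5 > r3 > 0


class TestMeasurement:
    def test_uniform_channel_ratio_is_exactly_one(self, clean_scene):
        img, _ = clean_scene
        labels = segment_nuclei(img)
        rings = cytoplasm_ring(labels)
        uni = MultiChannelImage({
            "nuclear_stain": img["nuclear_stain"],
            "flat": np.full(img.shape, 37.0),
        })
        tab = measure_nc(uni, labels, rings, ["flat"])
        assert np.allclose(tab["nc_ratio"], 1.0)

    def test_scaling_a_channel_leaves_ratio_unchanged(self, clean_scene):
        img, _ = clean_scene
        labels = segment_nuclei(img)
        rings = cytoplasm_ring(labels)
        t1 = measure_nc(img, labels, rings, ["bmal1"])
        scaled = MultiChannelImage({
            "nuclear_stain": img["nuclear_stain"],
            "bmal1": img["bmal1"] * 10.0,
        })
        t2 = measure_nc(scaled, labels, rings, ["bmal1"])
        assert np.allclose(t1["nc_ratio"], t2["nc_ratio"])

    def test_recovers_prescribed_ratios_noise_free(self, clean_scene):
        img, truth = clean_scene
        labels = segment_nuclei(img)
        rings = cytoplasm_ring(labels)
        tab = measure_nc(img, labels, rings, ["bmal1"])
        clean = tab[tab.qc_flags == ""]
        assert len(clean) == len(truth)
        for true_r, meas_r in _match_measured_to_truth(labels, tab, truth, "bmal1"):
            assert meas_r == pytest.approx(true_r, rel=0.01)

    def test_border_cell_flagged_not_dropped(self):
        stain = np.zeros((60, 60))
        rr, cc = np.ogrid[:60, :60]
        stain[(rr - 2) ** 2 + (cc - 30) ** 2 <= 49] = 500.0    # clipped by top edge
        stain[(rr - 35) ** 2 + (cc - 30) ** 2 <= 49] = 500.0   # interior
        img = MultiChannelImage({"nuclear_stain": stain, "p": np.full((60, 60), 5.0)})
        labels = segment_nuclei(img, min_area=10, sigma=0)
        rings = cytoplasm_ring(labels)
        tab = measure_nc(img, labels, rings, ["p"])
        flags = set(tab["qc_flags"])
        assert "" in flags and any("edge" in f for f in flags)

    def test_missing_channel_named_in_error(self, clean_scene):
        img, _ = clean_scene
        labels = segment_nuclei(img)
        rings = cytoplasm_ring(labels)
        with pytest.raises(ClockSyncError, match="clock"):
            measure_nc(img, labels, rings, ["clock"])


class TestSummary:
    def _table(self, a, b):
        n = len(a)
        rows = []
        for ch, vals in (("a", a), ("b", b)):
            for i, v in enumerate(vals):
                rows.append({"cell_id": i, "channel": ch, "nuc_mean": v,
                             "cyto_mean": 1.0, "nc_ratio": v, "qc_flags": ""})
        return pd.DataFrame(rows)

    def test_self_correlation_is_one(self, rng):
        a = rng.uniform(0.5, 3.0, 50)
        out = nc_summary(self._table(a, a), "a", "b")
        assert out["r"] == pytest.approx(1.0)

    def test_independent_ratios_uncorrelated(self, rng):
        a = rng.uniform(0.5, 3.0, 200)
        b = rng.uniform(0.5, 3.0, 200)
        out = nc_summary(self._table(a, b), "a", "b")
        assert abs(out["r"]) < 0.2

    def test_coupled_ratios_strongly_correlated(self, rng):
        a = rng.uniform(0.5, 3.0, 200)
        b = a + rng.normal(0, 0.15, 200)
        out = nc_summary(self._table(a, b), "a", "b")
        assert out["r"] > 0.8

    def test_too_few_shared_cells_rejected(self, rng):
        a = rng.uniform(0.5, 3.0, 2)
        with pytest.raises(ClockSyncError):
            nc_summary(self._table(a, a), "a", "b")
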