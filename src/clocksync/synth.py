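"""Synthetic data with ground truth for every pipeline stage.

Three generators emulate the three experimental data types:

* fixed-cell multichannel images with prescribed per-cell N/C ratios,
* time-lapse translocation datasets (label + intensity stacks) with a
  controlled responder fraction, per-cell latency/amplitude and an optional
  spatially correlated latency field,
* bioluminescence reporter traces (damped cosine + trend + noise) with
  programmed phase-shift events.

Every generator is fully determined by its scenario (including the seed):
one global seed spawns independent sub-streams per component, so the same
scenario always reproduces byte-identical outputs.  Truth tables list every
generated object exactly once.

Scale conventions: images are 16-bit-like float intensities, time-lapse
frames are 3 min apart (matching the live-imaging cadence), traces sample
every 10 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import PlacementError
from .imaging import MultiChannelImage
from .rhythm import BioluminescenceTrace
from .synchrony import SeriesMatrix

__all__ = [
    "ImagingScenario",
    "TimelapseScenario",
    "TraceScenario",
    "gen_fixed_cell_image",
    "gen_timelapse",
    "gen_biolum_trace",
    "TimelapseData",
]

_MAX_PLACEMENT_TRIES = 200


def _place_cells(rng, n, shape, margin, min_sep, tries_per_cell=_MAX_PLACEMENT_TRIES):
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    h, w = shape
    if margin * 2 >= min(h, w):
        raise PlacementError("margin leaves no interior")
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(tries_per_cell):
            c = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(np.linalg.norm(c - o) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"density too high: placed {len(centers)}/{n} cells "
                f"(min separation {min_sep}px in {h}x{w})"
            )
    return np.array(centers)


def _disk(shape, center, radius):
    r0, c0 = center
    rr = np.arange(max(0, int(r0 - radius - 1)), min(shape[0], int(r0 + radius + 2)))
    cc = np.arange(max(0, int(c0 - radius - 1)), min(shape[1], int(c0 + radius + 2)))
    if len(rr) == 0 or len(cc) == 0:
        return rr[:0], cc[:0]
    mask = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2 <= radius ** 2
    i, j = np.nonzero(mask)
    return rr[i], cc[j]


# ---------------------------------------------------------------------------
# fixed-cell images


@dataclass
class ImagingScenario:
    """Fixed-cell image layout and per-channel prescribed N/C ratios."""

    n_cells: int = 10
    shape: tuple[int, int] = (512, 512)
    nucleus_radius: tuple[float, float] = (8.0, 11.0)     # uniform range, px
    cytoplasm_radius: tuple[float, float] = (16.0, 20.0)  # uniform range, px
    nc_ratio: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"bmal1": (0.5, 3.0)}
    )
    cyto_intensity: float = 100.0
    nuclear_stain_intensity: float = 1000.0
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.nucleus_radius, self.cytoplasm_radius):
            if lo <= 0 or hi < lo:
                raise ValueError("radius ranges must be positive and ordered")
        if self.nucleus_radius[1] >= self.cytoplasm_radius[0]:
            raise ValueError("nucleus radius must stay below cytoplasm radius")


def gen_fixed_cell_image(scenario: ImagingScenario
                         ) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render one multichannel image plus its ground-truth table.

    Each cell is a cytoplasm disk at intensity c with a concentric nucleus
    disk at intensity r·c in every protein channel (r = that cell's true
    N/C ratio); the nuclear-stain channel marks nuclei only.  Noise is
    additive Gaussian, applied last.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_place, rng_param, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    r_cyto_max = scenario.cytoplasm_radius[1]
    centers = _place_cells(
        rng_place, scenario.n_cells, scenario.shape,
        margin=r_cyto_max + 4, min_sep=2 * r_cyto_max + 3,
    )
    n = scenario.n_cells
    r_nuc = rng_param.uniform(*scenario.nucleus_radius, n)
    r_cyt = rng_param.uniform(*scenario.cytoplasm_radius, n)
    ratios = {
        ch: rng_param.uniform(lo, hi, n) for ch, (lo, hi) in scenario.nc_ratio.items()
    }

    chans = {
        "nuclear_stain": np.full(scenario.shape, scenario.background, float)
    }
    for ch in scenario.nc_ratio:
        chans[ch] = np.full(scenario.shape, scenario.background, float)

    rows = []
    for k in range(n):
        nr, nc_ = _disk(scenario.shape, centers[k], r_nuc[k])
        cr, cc_ = _disk(scenario.shape, centers[k], r_cyt[k])
        chans["nuclear_stain"][nr, nc_] = scenario.nuclear_stain_intensity
        row = {
            "cell_id": k + 1, "row": centers[k][0], "col": centers[k][1],
            "r_nucleus": r_nuc[k], "r_cytoplasm": r_cyt[k],
        }
        for ch in scenario.nc_ratio:
            chans[ch][cr, cc_] = scenario.cyto_intensity
            chans[ch][nr, nc_] = ratios[ch][k] * scenario.cyto_intensity
            row[f"true_nc_ratio_{ch}"] = ratios[ch][k]
        rows.append(row)

    if scenario.noise_sd > 0:
        for ch in chans:
            noisy = chans[ch] + rng_noise.normal(0, scenario.noise_sd, scenario.shape)
            chans[ch] = np.clip(noisy, 0, None)

    return MultiChannelImage(chans), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time-lapse translocation datasets


@dataclass
class TimelapseScenario:
    """Stimulus-triggered sigmoidal translocation with controlled structure.

    Defaults emulate the live-imaging experiment: ~80 tracked cells, frames
    every 3 min for ~2 h, stimulus 30 min in, 80% responders whose relative
    nuclear intensity rises sigmoidally (baseline ~0.4 to plateau ~0.75)
    with per-cell latency and amplitude.  With ``spatial_correlation`` the
    latencies come from a smooth random spatial field, so neighboring cells
    respond together; otherwise latencies are independent across cells.
    """

    n_cells: int = 80
    n_frames: int = 41
    frame_interval_min: float = 3.0
    stimulus_time_min: float = 30.0
    responder_fraction: float = 0.8
    baseline_range: tuple[float, float] = (0.35, 0.45)
    amplitude_range: tuple[float, float] = (0.25, 0.45)
    latency_mean_min: float = 30.0
    latency_sd_min: float = 35.0
    rise_time_min: float = 5.0
    spatial_correlation: bool = False
    field_smooth_px: float = 12.0        # sigma on the 64x64 latency field grid
    shape: tuple[int, int] = (500, 500)
    nucleus_radius_px: float = 7.0
    cell_radius_px: float = 12.0
    motion_sd_px: float = 0.4
    rel_noise_sd: float = 0.04
    total_intensity: float = 10000.0
    pixel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        b0, b1 = self.baseline_range
        if not (0 <= b0 <= b1 <= 1):
            raise ValueError("baseline range must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder fraction must be in [0, 1]")
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ValueError("nucleus radius must be below cell radius")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass
class TimelapseData:
    """Generator output: ground truth always, rendered stacks on request."""

    truth: pd.DataFrame                  # cell_id, responder, latency_min, ...
    rel_nuc: np.ndarray                  # (n_cells, n_frames) noisy truth series
    coords: np.ndarray                   # (n_cells, 2) mean (x, y)
    times_min: np.ndarray
    nuclear_labels: np.ndarray | None = None   # (T, H, W)
    cell_labels: np.ndarray | None = None
    intensity: np.ndarray | None = None

    def series_matrix(self) -> SeriesMatrix:
        return SeriesMatrix(self.rel_nuc, self.coords, self.times_min,
                            self.truth["cell_id"].to_numpy())


def gen_timelapse(scenario: TimelapseScenario, render: bool = True) -> TimelapseData:
    """Generate a translocation dataset (and optionally render image stacks).

    The per-cell relative-nuclear-intensity program is

        rel(t) = b0 + a·sigmoid((t − t_stim − latency)/rise)   (responders)
        rel(t) = b0                                            (non-responders)

    plus additive Gaussian noise.  Rendered frames put rel·I_tot summed
    intensity in the nucleus disk and the remainder in the cytoplasmic
    annulus, so a perfect segmentation recovers rel exactly (up to noise).
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    rng_place, rng_assign, rng_field, rng_noise, rng_motion, rng_pix = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]

    centers = _place_cells(
        rng_place, sc.n_cells, sc.shape,
        margin=sc.cell_radius_px + 3, min_sep=2 * sc.cell_radius_px + 2,
    )
    n, T = sc.n_cells, sc.n_frames
    t = sc.times_min

    responders = rng_assign.random(n) < sc.responder_fraction
    b0 = rng_assign.uniform(*sc.baseline_range, n)
    amp = rng_assign.uniform(*sc.amplitude_range, n)
    # cap so rel stays within [0, 1]
    amp = np.minimum(amp, 1.0 - b0 - 0.05)

    if sc.spatial_correlation:
        grid = gaussian_filter(rng_field.standard_normal((64, 64)), sc.field_smooth_px)
        grid = (grid - grid.mean()) / grid.std()
        ij = np.clip((centers / np.array(sc.shape) * 64).astype(int), 0, 63)
        latency = sc.latency_mean_min + sc.latency_sd_min * grid[ij[:, 0], ij[:, 1]]
    else:
        latency = sc.latency_mean_min + sc.latency_sd_min * rng_field.standard_normal(n)
    latency = np.clip(latency, 0.0, None)

    rel = np.tile(b0[:, None], (1, T)).astype(float)
    sig = expit((t[None, :] - sc.stimulus_time_min - latency[:, None]) / sc.rise_time_min)
    rel[responders] += amp[responders, None] * sig[responders]
    rel_noisy = np.clip(rel + sc.rel_noise_sd * rng_noise.standard_normal((n, T)), 0.0, 1.0)

    truth = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "responder": responders,
        "latency_min": latency,
        "baseline": b0,
        "amplitude": amp,
        "x": centers[:, 1],
        "y": centers[:, 0],
    })

    data = TimelapseData(
        truth=truth, rel_nuc=rel_noisy,
        coords=centers[:, ::-1].copy(),  # (x, y)
        times_min=t.copy(),
    )
    if not render:
        return data

    h, w = sc.shape
    nuc_area = len(_disk(sc.shape, (h / 2, w / 2), sc.nucleus_radius_px)[0])
    walk = np.cumsum(rng_motion.normal(0, sc.motion_sd_px, (T, n, 2)), axis=0)
    nl = np.zeros((T, h, w), np.int32)
    cl = np.zeros((T, h, w), np.int32)
    im = np.zeros((T, h, w), float)
    for f in range(T):
        for k in range(n):
            c = np.clip(centers[k] + walk[f, k],
                        sc.cell_radius_px + 2,
                        np.array(sc.shape) - sc.cell_radius_px - 3)
            cr, cc_ = _disk(sc.shape, c, sc.cell_radius_px)
            nr, nc_ = _disk(sc.shape, c, sc.nucleus_radius_px)
            cl[f, cr, cc_] = k + 1
            nl[f, nr, nc_] = k + 1
            r = rel_noisy[k, f]
            cyto_area = len(cr) - len(nr)
            im[f, cr, cc_] = (1 - r) * sc.total_intensity / max(cyto_area, 1)
            im[f, nr, nc_] = r * sc.total_intensity / max(len(nr), 1)
    if sc.pixel_noise_sd > 0:
        im = np.clip(im + rng_pix.normal(0, sc.pixel_noise_sd, im.shape), 0, None)
    data.nuclear_labels, data.cell_labels, data.intensity = nl, cl, im
    return data


# ---------------------------------------------------------------------------
# bioluminescence traces


@dataclass
class TraceScenario:
    """Damped-cosine reporter trace with an optional phase-shift event."""

    period_h: float = 24.4
    amplitude: float = 100.0
    damping_per_h: float = 0.01
    mesor: float = 500.0
    trend_per_h: float = 0.0
    phase_h: float = 6.0                  # acrophase: first peak near this time
    noise_sd: float = 0.0
    sampling_min: float = 10.0
    duration_h: float = 96.0
    shift_event: tuple[float, float] | None = None   # (event time h, delta phi h)
    seed: int = 0

    def __post_init__(self):
        if self.period_h <= 0:
            raise ValueError("period must be positive")
        if self.duration_h < 2 * self.period_h:
            raise ValueError("duration must cover at least two periods")


def gen_biolum_trace(scenario: TraceScenario
                     ) -> tuple[BioluminescenceTrace, dict]:
    """One reporter trace plus its ground truth.

    y(t) = mesor + trend·t + A·exp(−damping·t)·cos(2π(t − φ(t))/τ) + noise,
    where a shift event at time t_e re-anchors the acrophase to φ + Δφ for
    all t ≥ t_e (a Δφ > 0 delays the subsequent peaks by Δφ hours).
    """
    sc = scenario
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed))
    t = np.arange(0.0, sc.duration_h + 1e-9, sc.sampling_min / 60.0)
    phi = np.full_like(t, sc.phase_h)
    if sc.shift_event is not None:
        t_e, dphi = sc.shift_event
        phi[t >= t_e] += dphi
    osc = sc.amplitude * np.exp(-sc.damping_per_h * t) * np.cos(
        2 * np.pi * (t - phi) / sc.period_h
    )
    y = sc.mesor + sc.trend_per_h * t + osc
    if sc.noise_sd > 0:
        y = y + rng.normal(0.0, sc.noise_sd, len(t))
    truth = {
        "period_h": sc.period_h,
        "phase_h": sc.phase_h,
        "oscillation": osc,
        "shift_event": sc.shift_event,
    }
    return BioluminescenceTrace(t, y, meta={"scenario": sc}), truth
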