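"""Single-cell translocation tracking and the positive-rate rule.

Live-cell experiments report BMAL1 nuclear accumulation as the *relative
nuclear intensity*: nuclear fluorescence divided by whole-cell fluorescence
(robust when the cytoplasmic signal is near the detection floor).  A cell is
called a translocation responder when its maximum post-stimulus fold change
exceeds the 75th percentile of the same quantity in the unstimulated
control population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ClockSyncError

__all__ = [
    "CellTrack",
    "PositiveRateResult",
    "link_tracks",
    "relative_nuclear_series",
    "max_fold_change",
    "positive_rate",
    "tracks_to_frame",
    "max_fold_changes",
]


@dataclass
class CellTrack:
    """One cell's per-frame measurements (times strictly increasing, min)."""

    cell_id: int
    frames: pd.DataFrame  # columns: frame, time_min, x, y, nuc_sum, cell_sum

    def __post_init__(self):
        t = self.frames["time_min"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ClockSyncError(f"track {self.cell_id}: frames not strictly time-ordered")

    def __len__(self) -> int:
        return len(self.frames)


def _frame_objects(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ids, centroids[row, col]) of labeled objects in one frame."""
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        return ids, np.empty((0, 2))
    cent = np.asarray(ndi.center_of_mass(np.ones_like(labels), labels, ids))
    return ids, cent


def link_tracks(
    nuclear_labels: np.ndarray,
    cell_labels: np.ndarray,
    intensity: np.ndarray,
    times_min: np.ndarray | None = None,
    max_disp: float = 10.0,
) -> list[CellTrack]:
    """Greedy nearest-centroid linking of nuclei across frames.

    ``nuclear_labels`` and ``cell_labels`` are (T, H, W) label stacks sharing
    per-frame object labels is *not* assumed — nuclei are matched to cells by
    centroid containment per frame.  ``intensity`` is the (T, H, W) reporter
    stack; per frame the track records summed intensity over the nucleus and
    over the whole cell footprint.  Matches farther than ``max_disp`` pixels
    are refused: the old track ends and a new one starts (identities are
    never swapped across a long jump).
    """
    if nuclear_labels.shape != cell_labels.shape or nuclear_labels.shape != intensity.shape:
        raise ClockSyncError("label/intensity stacks must share (T, H, W) shape")
    T = nuclear_labels.shape[0]
    if times_min is None:
        times_min = np.arange(T, dtype=float)

    next_id = 0
    active: dict[int, np.ndarray] = {}      # track id -> last centroid
    rows: dict[int, list] = {}

    for f in range(T):
        nl, cl, im = nuclear_labels[f], cell_labels[f], intensity[f]
        ids, cents = _frame_objects(nl)
        assigned: dict[int, int] = {}       # object index -> track id
        if active and len(ids):
            tids = list(active)
            prev = np.stack([active[t] for t in tids])
            d = np.linalg.norm(prev[:, None, :] - cents[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_t, used_o = set(), set()
            for ti, oi in order:
                if d[ti, oi] > max_disp:
                    break
                if ti in used_t or oi in used_o:
                    continue
                assigned[int(oi)] = tids[ti]
                used_t.add(int(ti))
                used_o.add(int(oi))
        new_active = {}
        if len(ids):
            nuc_sums = ndi.sum_labels(im, nl, ids)
            rr = np.clip(np.round(cents[:, 0]).astype(int), 0, cl.shape[0] - 1)
            cc = np.clip(np.round(cents[:, 1]).astype(int), 0, cl.shape[1] - 1)
            cell_ids_here = cl[rr, cc]
            cell_sums = np.where(
                cell_ids_here > 0,
                ndi.sum_labels(im, cl, cell_ids_here),
                nuc_sums,
            )
        for oi, (obj_id, cent) in enumerate(zip(ids, cents)):
            tid = assigned.get(oi)
            if tid is None:
                tid = next_id
                next_id += 1
                rows[tid] = []
            rows[tid].append({
                "frame": f, "time_min": float(times_min[f]),
                "x": float(cent[1]), "y": float(cent[0]),
                "nuc_sum": float(nuc_sums[oi]),
                "cell_sum": float(cell_sums[oi]),
            })
            new_active[tid] = cent
        active = new_active

    return [CellTrack(tid, pd.DataFrame(r)) for tid, r in sorted(rows.items())]


def relative_nuclear_series(track: CellTrack) -> pd.Series:
    """Relative nuclear intensity nuc_sum / cell_sum per frame.

    Frames with zero whole-cell intensity are returned as NaN (missing),
    indexed by time in minutes.
    """
    f = track.frames
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(f["cell_sum"] > 0, f["nuc_sum"] / f["cell_sum"], np.nan)
    return pd.Series(rel, index=f["time_min"].to_numpy(), name=track.cell_id)


def max_fold_change(series: pd.Series, stimulus_time: float,
                    baseline_window: tuple[float, float] | None = None,
                    search_end: float | None = None) -> float:
    """Maximum post-stimulus value divided by the pre-stimulus baseline mean.

    The baseline defaults to all frames strictly before ``stimulus_time``.
    NaN frames are ignored; an empty or zero baseline is an error.
    """
    t = np.asarray(series.index, dtype=float)
    v = np.asarray(series, dtype=float)
    if baseline_window is None:
        base = v[(t < stimulus_time) & np.isfinite(v)]
    else:
        b0, b1 = baseline_window
        base = v[(t >= b0) & (t < b1) & np.isfinite(v)]
    if base.size == 0:
        raise ClockSyncError("empty baseline window")
    baseline = base.mean()
    if baseline <= 0:
        raise ClockSyncError("zero baseline: fold change undefined")
    hi = t <= search_end if search_end is not None else np.ones_like(t, bool)
    post = v[(t >= stimulus_time) & hi & np.isfinite(v)]
    if post.size == 0:
        raise ClockSyncError("no post-stimulus frames")
    return float(post.max() / baseline)


def max_fold_changes(tracks: list[CellTrack], stimulus_time: float, **kw) -> np.ndarray:
    """Per-cell maximum fold changes for a list of tracks."""
    return np.array([
        max_fold_change(relative_nuclear_series(tr), stimulus_time, **kw)
        for tr in tracks
    ])


@dataclass
class PositiveRateResult:
    """Fraction of treated cells above the control-quantile threshold."""

    threshold: float
    n_positive: int
    n_total: int
    rate: float
    quantile: float
    treated_fold_changes: np.ndarray
    control_fold_changes: np.ndarray


def positive_rate(
    treated,
    control,
    q: float = 0.75,
    stimulus_time: float | None = None,
) -> PositiveRateResult:
    """Positive-rate rule: threshold at the control q-quantile of max fold change.

    ``treated`` / ``control`` are either arrays of per-cell maximum fold
    changes or lists of :class:`CellTrack` (then ``stimulus_time`` is
    required).  The threshold is the linearly interpolated (type-7) quantile
    of the control values; positivity is *strictly* above threshold.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")

    def _fcs(arm):
        if len(arm) == 0:
            raise ClockSyncError("empty arm")
        if isinstance(arm[0], CellTrack):
            if stimulus_time is None:
                raise ValueError("stimulus_time required when passing tracks")
            return max_fold_changes(list(arm), stimulus_time)
        return np.asarray(arm, dtype=float)

    tfc, cfc = _fcs(treated), _fcs(control)
    thr = float(np.quantile(cfc, q))  # numpy default = linear (type 7)
    n_pos = int((tfc > thr).sum())
    return PositiveRateResult(
        threshold=thr, n_positive=n_pos, n_total=len(tfc),
        rate=n_pos / len(tfc), quantile=q,
        treated_fold_changes=tfc, control_fold_changes=cfc,
    )


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    """Tidy per-cell per-frame table (round-trips through CSV)."""
    out = []
    for tr in tracks:
        f = tr.frames.copy()
        f.insert(0, "cell_id", tr.cell_id)
        out.append(f)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["cell_id", "frame", "time_min", "x", "y", "nuc_sum", "cell_sum"]
    )
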