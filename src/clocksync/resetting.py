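"""Phase resetting analyses: phase shifts, fold changes, PRCs, protocol sweeps.

Conventions
-----------
* Runs start from the limit-cycle CT0 anchor state, so simulation time is
  circadian time until the protocol perturbs the clock.
* The phase shift Δφ compares late-cycle Per2 mRNA peak times between the
  perturbed and unperturbed runs, skipping two full cycles after protocol
  end for the transient to decay, and is reported wrapped into
  (−τ/2, τ/2] with **positive = phase advance** (perturbed peaks earlier).
* Fold change of a species is max(perturbed) / max(unperturbed) over the
  same window starting at protocol onset — the ratio of maximum induction
  levels.  ``baseline="onset"`` divides instead by the unperturbed level at
  the onset instant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import OscillationLostError, UndefinedFoldChangeError
from .models import ClockModel
from .protocols import (
    DEX_PROTOCOL_DURATION_H,
    DEX_PROTOCOL_FACTOR,
    SyncProtocol,
)
from .simulate import LimitCycle, Trajectory, find_limit_cycle, integrate, peak_times

__all__ = [
    "PhaseShiftResult",
    "PRCResult",
    "ResettingExperiment",
    "phase_shift",
    "fold_change",
    "phase_response_curve",
    "sweep_protocols",
    "simulate_ck2_inhibition",
    "PAPER_FACTORS",
    "PAPER_DURATIONS",
    "DEFAULT_CT_GRID",
    "wrap_phase",
]

# Factorial sweep used for choosing the stimulus arm parameters.
PAPER_FACTORS = (1.0, 2.0, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0)
PAPER_DURATIONS = (0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)
# Hourly protocol onsets between circadian time 8 and 32 h.
DEFAULT_CT_GRID = tuple(float(ct) for ct in range(8, 33))

FC_WINDOW_H = 24.0
SKIP_CYCLES = 2
MEASURE_CYCLES = 3


def wrap_phase(dphi: float | np.ndarray, period: float) -> float | np.ndarray:
    """Wrap a phase difference into (−τ/2, τ/2]."""
    return -((-dphi + period / 2) % period - period / 2)


@dataclass
class PhaseShiftResult:
    """Phase shift of Per2 plus induction fold changes for one protocol."""

    shift: float                       # h; positive = advance
    fold_change_phospho: float
    fold_change_per2: float
    period: float
    protocol: SyncProtocol


@dataclass
class PRCResult:
    """Phase response curve: one phase shift / fold change per onset CT."""

    ct_grid: np.ndarray
    shifts: np.ndarray
    fold_changes_phospho: np.ndarray
    fold_changes_per2: np.ndarray
    period: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ct": self.ct_grid,
            "phase_shift_h": self.shifts,
            "fc_phospho": self.fold_changes_phospho,
            "fc_per2": self.fold_changes_per2,
        })


def fold_change(
    perturbed: Trajectory,
    unperturbed: Trajectory,
    model: ClockModel,
    species_role: str,
    onset: float,
    window: float = FC_WINDOW_H,
    baseline: str = "max",
) -> float:
    """Induction fold change of a tagged species after a protocol onset."""
    a = perturbed.window(onset, onset + window).series_for(model, species_role)
    b = unperturbed.window(onset, onset + window).series_for(model, species_role)
    if baseline == "max":
        denom = float(b.max())
    elif baseline == "onset":
        denom = float(b[0])
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if denom <= 0:
        raise UndefinedFoldChangeError(
            f"undefined fold change: zero baseline for {species_role}"
        )
    return float(a.max()) / denom


class ResettingExperiment:
    """Caches the limit cycle and the unperturbed reference run for a model.

    All protocol evaluations against one model share the same converged
    anchor state and reference trajectory, which keeps sweeps and PRCs at
    one perturbed integration per protocol.
    """

    def __init__(self, model: ClockModel, total: float | None = None):
        self.model = model
        self.cycle: LimitCycle = find_limit_cycle(model)
        tau = self.cycle.period
        # longest protocol ends by t_start<2tau + 8 h; then skip+measure cycles
        self.total = total or (2 * tau + 8.0 + (SKIP_CYCLES + MEASURE_CYCLES + 1) * tau)
        self.reference = integrate(model, self.cycle.ct0_state, (0.0, self.total))
        self._ref_per2_peaks = peak_times(
            self.reference.times, self.reference.series_for(model, "per2_mrna")
        )

    def run(self, protocol: SyncProtocol | None) -> Trajectory:
        return integrate(self.model, self.cycle.ct0_state, (0.0, self.total),
                         protocol=protocol)

    def phase_shift(self, protocol: SyncProtocol) -> PhaseShiftResult:
        """Δφ of Per2 vs the unperturbed run, plus induction fold changes."""
        tau = self.cycle.period
        if protocol.t_end + (SKIP_CYCLES + MEASURE_CYCLES) * tau > self.total:
            raise ValueError("protocol window leaves fewer than the required post cycles")
        pert = self.run(protocol)
        fc_p = fold_change(pert, self.reference, self.model,
                           "phospho_bmal1_clock_nuclear", protocol.t_start)
        fc_m = fold_change(pert, self.reference, self.model, "per2_mrna", protocol.t_start)
        t_min = protocol.t_end + SKIP_CYCLES * tau
        ref_pk = self._ref_per2_peaks[self._ref_per2_peaks >= t_min]
        per2 = pert.series_for(self.model, "per2_mrna")
        pert_pk = peak_times(pert.times, per2)
        pert_pk = pert_pk[pert_pk >= t_min]
        n = min(len(ref_pk), len(pert_pk), MEASURE_CYCLES)
        if n == 0:
            raise OscillationLostError("oscillation abolished by protocol (no late Per2 peaks)")
        # amplitude sanity on the tail
        tail = pert.window(t_min, self.total).series_for(self.model, "per2_mrna")
        ref_tail = self.reference.window(t_min, self.total).series_for(self.model, "per2_mrna")
        if (tail.max() - tail.min()) < 0.05 * (ref_tail.max() - ref_tail.min()):
            raise OscillationLostError("oscillation abolished by protocol (amplitude collapsed)")
        diffs = wrap_phase(pert_pk[-n:] - ref_pk[-n:], tau)
        shift = float(wrap_phase(-np.mean(diffs), tau))  # positive = advance
        return PhaseShiftResult(shift, fc_p, fc_m, tau, protocol)


def phase_shift(model: ClockModel, protocol: SyncProtocol,
                experiment: ResettingExperiment | None = None) -> PhaseShiftResult:
    exp = experiment or ResettingExperiment(model)
    return exp.phase_shift(protocol)


def phase_response_curve(
    model: ClockModel,
    template: SyncProtocol | None = None,
    ct_grid: Sequence[float] = DEFAULT_CT_GRID,
    experiment: ResettingExperiment | None = None,
) -> PRCResult:
    """Phase shift and fold change as a function of protocol onset CT."""
    if not len(ct_grid):
        raise ValueError("ct_grid must be non-empty")
    exp = experiment or ResettingExperiment(model)
    template = template or SyncProtocol(0.0, DEX_PROTOCOL_DURATION_H, DEX_PROTOCOL_FACTOR)
    shifts, fcp, fcm = [], [], []
    for ct in ct_grid:
        r = exp.phase_shift(template.at_onset(float(ct)))
        shifts.append(r.shift)
        fcp.append(r.fold_change_phospho)
        fcm.append(r.fold_change_per2)
    return PRCResult(np.asarray(ct_grid, float), np.asarray(shifts),
                     np.asarray(fcp), np.asarray(fcm), exp.cycle.period)


def sweep_protocols(
    model: ClockModel,
    factors: Iterable[float] = PAPER_FACTORS,
    durations: Iterable[float] = PAPER_DURATIONS,
    ct_grid: Iterable[float] = (15.0,),
    experiment: ResettingExperiment | None = None,
) -> pd.DataFrame:
    """Full factorial protocol sweep; failures are recorded per row."""
    exp = experiment or ResettingExperiment(model)
    rows = []
    for f in factors:
        for d in durations:
            for ct in ct_grid:
                row = {"factor": f, "duration": d, "ct": ct,
                       "phase_shift_h": np.nan, "fc_phospho": np.nan,
                       "fc_per2": np.nan, "error": ""}
                try:
                    r = exp.phase_shift(SyncProtocol(float(ct), float(d), float(f)))
                    row.update(phase_shift_h=r.shift, fc_phospho=r.fold_change_phospho,
                               fc_per2=r.fold_change_per2)
                except Exception as e:  # noqa: BLE001 — sweep must continue
                    row["error"] = f"{type(e).__name__}: {e}"
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_ck2_inhibition(
    model: ClockModel,
    onset_ct: float = 15.0,
    experiment: ResettingExperiment | None = None,
) -> dict:
    """Three-arm in silico experiment at one onset CT.

    ``dex``: 15-fold phosphorylation-rate increase for 2 h.
    ``dex_go289``: rate set to zero for 2 h (complete CK2 inhibition during
    the stimulus window).
    ``unstimulated``: no protocol.
    Returns trajectories for all arms and phase-shift results for the two
    stimulated arms.
    """
    exp = experiment or ResettingExperiment(model)
    dex = SyncProtocol(onset_ct, DEX_PROTOCOL_DURATION_H, DEX_PROTOCOL_FACTOR)
    go = SyncProtocol(onset_ct, DEX_PROTOCOL_DURATION_H, 0.0)
    return {
        "unstimulated": exp.reference,
        "dex": exp.run(dex),
        "dex_go289": exp.run(go),
        "shift_dex": exp.phase_shift(dex),
        "shift_dex_go289": exp.phase_shift(go),
        "period": exp.cycle.period,
    }
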