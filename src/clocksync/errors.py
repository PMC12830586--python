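"""Exception hierarchy for the clocksync pipeline."""


class ClockSyncError(Exception):
    """Base class for all clocksync errors."""


class ModelDefinitionError(ClockSyncError):
    """Malformed model file: missing species, unresolvable tags, bad expressions."""


class IntegrationError(ClockSyncError):
    """The ODE solver failed to produce a trajectory."""


class NegativeStateError(IntegrationError):
    """A concentration went negative beyond tolerance; carries the species name."""

    def __init__(self, species: str, value: float):
        self.species = species
        self.value = value
        super().__init__(f"species {species!r} reached {value:.3e} < 0 during integration")


class NoLimitCycleError(ClockSyncError):
    """Dynamics damped to a fixed point (or never converged to a periodic orbit)."""


class OscillationLostError(ClockSyncError):
    """A protocol abolished the oscillation in the perturbed run."""


class UndefinedFoldChangeError(ClockSyncError):
    """Fold change requested against a zero baseline."""


class ConstantSeriesError(ClockSyncError):
    """A cell's series has zero variance; carries the offending cell id."""


class NetworkConvergenceError(ClockSyncError):
    """Graphical lasso failed to converge / failed its stationarity check."""


class DegenerateGeometryError(ClockSyncError):
    """Delaunay triangulation impossible (e.g. all points collinear)."""


class PlacementError(ClockSyncError):
    """Synthetic cell placement failed: requested density too high."""
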