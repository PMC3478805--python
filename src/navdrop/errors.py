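"""Exception hierarchy.

All domain errors derive from :class:`NavdropError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class NavdropError(Exception):
    """Base class for all navdrop domain errors."""


class InvalidProfileError(NavdropError):
    """A gait profile or sensor model violates its invariants."""


class OverStrainError(NavdropError):
    """Simulated elongation exceeds the sensor's maximal safe strain.

    The strainable film tolerates strain only up to ``max_strain_frac`` of its
    rest length; beyond that the material would be damaged, so the simulator
    refuses rather than silently clipping.
    """


class DegenerateSweepError(NavdropError):
    """Calibration sweep has no capacitance spread; no line can be fitted."""


class CannotSyncError(NavdropError):
    """Fewer than two valid sync words; streams cannot be aligned."""


class DegenerateFrameError(NavdropError):
    """Reference markers coincide; the local coordinate frame is undefined."""


class AxisUndefinedError(NavdropError):
    """Point cloud is (near-)isotropic; its major axis is not meaningful."""


class CannotSegmentError(NavdropError):
    """No significant periodicity found; steps cannot be segmented."""


class ParseError(NavdropError):
    """An input file violates the expected format."""
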