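"""Exception hierarchy for stentbench.

All package errors derive from :class:`StentBenchError` so callers can catch
one base class; each also derives from the closest builtin category.
"""


class StentBenchError(Exception):
    """Base class for all stentbench errors."""


class InvalidParameterError(StentBenchError, ValueError):
    """A numeric or structural parameter violates its contract."""


class PresetLookupError(StentBenchError, KeyError):
    """Unknown system-preset name."""


class GeometryError(StentBenchError, ValueError):
    """Phantom geometry is physically inconsistent (e.g. stent wider than lumen)."""


class ResolutionError(StentBenchError, ValueError):
    """Ground-truth grid does not oversample the target detector grid adequately."""


class OutOfBoundsError(StentBenchError, ValueError):
    """A sampling line or window exits the image volume."""


class MeasurementFailureError(StentBenchError, RuntimeError):
    """Too few usable profiles to report a measurement."""


class PairingError(StentBenchError, ValueError):
    """Paired-design inputs cannot be matched item by item."""


class DegenerateSampleError(StentBenchError, ValueError):
    """A statistical routine received a sample with no usable variation."""
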