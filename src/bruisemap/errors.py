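"""Exception hierarchy for the bruisemap pipeline.

Every stage raises a subclass of :class:`BruisemapError` so that batch
drivers can distinguish pipeline failures from programming errors.
"""


class BruisemapError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BruisemapError):
    """Input file does not match the expected layout (shape, columns, ...)."""


class ValidationError(BruisemapError):
    """Input violates a domain invariant (negative force, impossible geometry)."""


class ParameterError(BruisemapError):
    """Configuration or physical parameter out of its admissible range."""


class NoContactError(BruisemapError):
    """No frame in the recording exceeds the contact force floor."""


class NoImpactError(BruisemapError):
    """An all-zero energy map has no impact centre to locate."""


class NoZoneError(BruisemapError):
    """Segmentation produced an empty foreground: no death zone detected."""


class NoTissueError(BruisemapError):
    """A section image contains no tissue/background boundary to trace."""


class ResamplingError(BruisemapError):
    """Too few defined points to interpolate a profile."""


class RegistrationError(BruisemapError):
    """Profiles overlap on fewer than the minimum number of points."""


class DegenerateSeriesError(BruisemapError):
    """All points were masked away; no series remains to correlate."""


class SimulationError(BruisemapError):
    """The impact simulator left its physically sane envelope."""
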