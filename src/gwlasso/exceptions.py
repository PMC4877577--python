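"""Exception hierarchy.

Config/input problems and numerical failures are kept distinct so the CLI
can map them to different exit codes (2 and 3 respectively).
"""


class GWLError(Exception):
    """Base class for all package errors."""


class ConfigError(GWLError):
    """Invalid configuration: missing columns, bad role mapping, bad paths."""


class InputError(GWLError):
    """Invalid data: non-finite coordinates, missing values, shape mismatch."""


class ParameterError(GWLError):
    """Invalid parameter value: non-positive bandwidth, empty grid, etc."""


class DegenerateFitError(GWLError):
    """A local fit cannot be computed (e.g. all effective outcomes equal)."""


class NumericalError(GWLError):
    """A numerical procedure failed irrecoverably (e.g. calibration of k)."""
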