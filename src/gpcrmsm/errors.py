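"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`GpcrMsmError`, so callers
(notably the CLI) can translate failures into exit codes without matching on
message text.
"""


class GpcrMsmError(Exception):
    """Base class for all package errors."""


class FormatError(GpcrMsmError, ValueError):
    """A file does not conform to its declared format."""


class EmptyInputError(GpcrMsmError, ValueError):
    """An input contained no usable records."""


class ConsistencyError(GpcrMsmError, ValueError):
    """Structurally valid inputs that disagree with each other."""


class SelectionError(GpcrMsmError, ValueError):
    """A selection query failed to parse or resolved unusably."""


class TopologyError(GpcrMsmError, ValueError):
    """Required atoms are missing from the topology."""


class ParameterError(GpcrMsmError, ValueError):
    """An argument is outside its documented domain."""


class SpecError(GpcrMsmError, ValueError):
    """A synthetic-data specification is invalid."""


class ModelError(GpcrMsmError, ValueError):
    """A kinetic model violates its invariants (e.g. non-stochastic rows)."""


class DataError(GpcrMsmError, ValueError):
    """Insufficient or malformed trajectory/sequence data for an estimate."""


class EstimationError(GpcrMsmError, ValueError):
    """Model estimation cannot proceed (e.g. all-zero counts)."""


class DegenerateGeometryError(GpcrMsmError, ValueError):
    """A geometric quantity is undefined for the given coordinates."""


class ConfigError(GpcrMsmError, ValueError):
    """Pipeline configuration is invalid."""
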