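"""Exception hierarchy for the clonemut pipeline.

Every stage raises a subclass of :class:`CloneMutError`, so callers can
distinguish bad user input (configuration, file formats) from internal
data-consistency problems (e.g. a variant whose REF disagrees with the
reference genome it is being interpreted against).
"""


class CloneMutError(Exception):
    """Base class for all clonemut errors."""


class InputError(CloneMutError):
    """A required input file is missing or unreadable."""


class ConfigurationError(CloneMutError):
    """Invalid parameter combination (thresholds, sample names, sizes)."""


class FormatError(CloneMutError):
    """A file parsed but violated its format contract."""


class CoordinateError(CloneMutError):
    """A 1-based inclusive coordinate query fell outside its chromosome."""


class DataConsistencyError(CloneMutError):
    """Two inputs disagree, e.g. variant REF vs reference genome base."""


class NormalizationError(CloneMutError):
    """An empty or zero-norm spectrum cannot be normalized."""


class DegenerateTableError(CloneMutError):
    """A 2x2 contingency table with a zero margin cannot be tested."""


class SimulationError(CloneMutError):
    """The synthetic-data generator could not satisfy its constraints."""
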