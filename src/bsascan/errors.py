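"""Exception hierarchy shared across the pipeline stages."""


class BsaScanError(Exception):
    """Base class for all package errors."""


class ConfigError(BsaScanError):
    """A configuration value is missing, malformed, or out of range."""


class SimulationError(BsaScanError):
    """The generative model could not satisfy the request (e.g. too few
    plants of one phenotype class to fill a bulk)."""


class InputError(BsaScanError):
    """An input file is missing required samples, fields or columns."""


class ContractError(BsaScanError):
    """A documented precondition was violated by the caller (e.g. unsorted
    sites, zero-depth site reaching the ED statistic)."""


class AnalysisError(BsaScanError):
    """The scan cannot proceed (e.g. fewer than two defined windows)."""


class OutputError(BsaScanError):
    """An output contract was violated (e.g. overlapping BED regions)."""
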