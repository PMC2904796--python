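"""Exception hierarchy for chronoscreen."""


class ChronoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChronoscreenError):
    """Invalid configuration value or combination."""


class ParseError(ChronoscreenError):
    """Malformed input table; message names the offending row/column."""


class SimulationError(ChronoscreenError):
    """Simulation reached an invalid state (e.g. pool extinct)."""


class InputError(ChronoscreenError):
    """Inconsistent inputs handed to an analysis step."""
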