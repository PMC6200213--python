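"""Exception hierarchy for the samph pipeline."""


class SamphError(Exception):
    """Base class for all samph errors."""


class InputError(SamphError, ValueError):
    """Unreadable, malformed or out-of-contract input data."""


class SchemaError(InputError):
    """A tabular input is missing required columns or contains invalid labels."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate for the requested operation
    (constant signal, silent envelope, too short for the filter)."""


class ConfigurationError(SamphError, ValueError):
    """An analysis parameter is outside its meaningful range."""
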