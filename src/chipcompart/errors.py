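"""Exception hierarchy.

``ConfigurationError`` covers bad profiles/configs (user input that never
touches data); ``DataError`` covers malformed or inconsistent data files.
The CLI maps them to distinct exit codes.
"""


class ChipCompartError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChipCompartError):
    """A configuration file or option is missing or invalid."""


class DataError(ChipCompartError):
    """An input data file is malformed or internally inconsistent."""
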