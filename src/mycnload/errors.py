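"""Exception hierarchy shared across the package.

Validation problems (bad configuration, malformed files) are distinguished
from data problems (inputs that parse but cannot be analysed) so the CLI can
map them to distinct exit codes.
"""


class MycnloadError(Exception):
    """Base class for all package errors."""


class ParseError(MycnloadError):
    """A file failed to parse; the message names the file/line where known."""


class ConfigError(MycnloadError):
    """Invalid configuration or arguments (missing samples, bad thresholds)."""


class DataError(MycnloadError):
    """Inputs parsed but are unusable for the requested analysis."""
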