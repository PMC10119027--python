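"""Exception types shared across wgdkit."""


class WgdkitError(Exception):
    """Base class for all wgdkit errors."""


class FormatError(WgdkitError, ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(WgdkitError, ValueError):
    """Two inputs that must describe the same objects disagree."""


class ConfigurationError(WgdkitError, ValueError):
    """A parameter set is internally infeasible or refers to missing data."""
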