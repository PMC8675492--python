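"""Exception hierarchy shared across mrkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigError(MRKitError):
    """Invalid configuration: missing columns, bad YAML, unknown options."""


class DataError(MRKitError):
    """Input data cannot be used: empty tables, no usable instruments."""


class EstimationError(MRKitError):
    """An estimator cannot produce a result on the given input."""
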