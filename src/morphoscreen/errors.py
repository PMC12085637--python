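"""Package exception hierarchy, mapped to CLI exit codes."""


class MorphoscreenError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(MorphoscreenError):
    """Invalid configuration or unknown backbone."""

    exit_code = 2


class DataError(MorphoscreenError):
    """Invalid, missing or inconsistent input data."""

    exit_code = 3


class TrainError(MorphoscreenError):
    """Training failure (e.g. non-finite loss)."""

    exit_code = 4
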