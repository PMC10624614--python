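"""Exception hierarchy; the CLI maps each class to a distinct exit code."""


class SlowwaveError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(SlowwaveError):
    """Invalid configuration (schema violation, inconsistent parameters)."""

    exit_code = 2


class DataError(SlowwaveError):
    """Malformed or insufficient input data."""

    exit_code = 3


class ComputeError(SlowwaveError):
    """A computation could not be carried out on otherwise valid inputs."""

    exit_code = 4
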