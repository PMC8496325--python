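class SynorthError(Exception):
    """Base class for all synorth errors."""


class DataError(SynorthError):
    """Malformed or inconsistent input data (exit code 2 from the CLI)."""
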