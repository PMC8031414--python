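"""Exception types shared across the package."""


class RepeatSpanError(Exception):
    """Base class for package errors."""


class FormatError(RepeatSpanError):
    """A file did not conform to its declared format.

    Carries an optional line number so users can locate the offending
    record in large FASTQ/SAM files.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
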