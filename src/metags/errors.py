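"""Exception hierarchy for metags."""


class MetaGSError(Exception):
    """Base class for all metags errors."""


class InvalidFrequencyError(MetaGSError):
    """An allele frequency lies outside the open interval (0, 1)."""


class MonomorphicSNPError(InvalidFrequencyError):
    """A SNP is fixed (allele frequency 0 or 1) in the population."""


class DomainError(MetaGSError):
    """A numeric argument lies outside its valid domain."""


class AlignmentError(MetaGSError):
    """Vector/matrix dimensions or SNP/individual orderings do not agree."""


class SnpSetMismatchError(AlignmentError):
    """Populations carry different SNP lists; harmonize them first
    (see :mod:`metags.sumstat_ops` for summary-statistic imputation)."""


class SingularSystemError(MetaGSError):
    """A coefficient matrix could not be factorized."""

    def __init__(self, message: str, condition: float | None = None):
        if condition is not None:
            message = f"{message} (condition estimate {condition:.3e})"
        super().__init__(message)
        self.condition = condition


class FileFormatError(MetaGSError):
    """A file does not conform to the expected on-disk format."""

    def __init__(self, message: str, *, path=None, offset=None, line=None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if offset is not None:
            loc.append(f"byte offset {offset}")
        if loc:
            message = f"{message} [{': '.join(loc)}]"
        super().__init__(message)
        self.path = path
        self.offset = offset
        self.line = line


class ConfigError(MetaGSError):
    """A run configuration is invalid (missing path, out-of-range value)."""
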