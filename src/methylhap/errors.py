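"""Exception hierarchy used across the package."""


class MethylhapError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MethylhapError):
    """A file violates its dialect; message carries the offending line number."""


class AlignmentError(MethylhapError):
    """A genomic coordinate does not resolve to a known CpG site."""


class SchemaError(MethylhapError):
    """A table or matrix violates the expected schema."""


class EmptyCohortError(MethylhapError):
    """A filter or estimator was left with no samples."""


class PairingError(MethylhapError):
    """Paired analysis requested but tumor/normal pairing is incomplete."""


class UndefinedTestError(MethylhapError):
    """A statistical test has no valid data (empty group, all-zero differences)."""


class StratificationError(MethylhapError):
    """Cross-validation folds cannot contain every class."""


class PipelineError(MethylhapError):
    """A pipeline stage failed; message names the stage."""
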