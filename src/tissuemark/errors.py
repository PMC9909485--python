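"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: validation errors -> 2, format
errors -> 3, empty-result errors -> 4.
"""


class TissuemarkError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(TissuemarkError):
    """Input violates a documented invariant (duplicate IDs, bad config...)."""

    exit_code = 2


class FormatError(TissuemarkError):
    """A file does not conform to its declared dialect (GCT, TSV, GMT)."""

    exit_code = 3


class EmptyResultError(TissuemarkError):
    """A filtering step removed everything; downstream stages cannot run."""

    exit_code = 4
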