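"""Exception types shared across the package."""


class ParseError(ValueError):
    """A tabular input file is malformed (reported with a line number)."""


class ValidationError(ValueError):
    """A value violates a documented invariant (bad config field, bad label...)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class NoCandidatesError(PipelineError):
    """The differential screen produced an empty candidate pool."""
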