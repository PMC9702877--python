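class FragkinError(Exception):
    """Base class for package errors."""


class SpecificationError(FragkinError):
    """A simulation or analysis specification violates its invariants."""


class AnalysisError(FragkinError):
    """An analysis operation received input it cannot meaningfully process."""
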