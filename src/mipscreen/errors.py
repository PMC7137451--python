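"""Exception hierarchy."""


class MipscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(MipscreenError):
    """Input data violated a structural or domain invariant."""


class AnalysisError(MipscreenError):
    """An analysis step could not be carried out on valid input."""
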