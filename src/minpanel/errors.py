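"""Exception hierarchy shared across the package."""


class MinPanelError(Exception):
    """Base class for all minpanel errors."""


class FormatError(MinPanelError):
    """A table or cell does not match the expected text layout."""


class ValidationError(MinPanelError):
    """Input content is syntactically readable but semantically invalid."""


class ParameterError(MinPanelError):
    """A function argument is outside its allowed range."""


class EmptyInputError(MinPanelError):
    """An operation was asked to summarise nothing."""


class UndefinedResultError(MinPanelError):
    """The requested quantity is undefined for this input (e.g. all calls missing)."""


class StrandAmbiguityError(MinPanelError):
    """A palindromic SNP cannot be strand-harmonized without an explicit mapping."""


class AlignmentError(MinPanelError):
    """Two tables that must share samples/markers do not line up."""
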