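"""Exception hierarchy shared by all analysis modules."""


class TrajscopeError(Exception):
    """Base class for all errors raised by trajscope."""


class ParseError(TrajscopeError):
    """A text input (PDB, selection, label file) could not be parsed."""


class FormatError(TrajscopeError):
    """A binary input violates its format (size mismatch, bad magic)."""


class UnsupportedFeatureError(FormatError):
    """The input uses a format feature this reader does not support."""


class SelectionError(TrajscopeError):
    """A selection expression is syntactically invalid."""


class DisconnectedNetworkError(TrajscopeError):
    """An elastic network has no springs connecting its nodes."""


class DegenerateInputError(TrajscopeError):
    """An input is formally valid but carries no usable signal."""
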