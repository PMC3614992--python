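"""Exception hierarchy.

``FormatError`` marks malformed files (duplicate ids, ragged rows, non-numeric
cells); ``InputError`` marks well-formed but unusable input (too few samples,
asymmetric similarity, empty result after filtering). Both derive from
``ChronoqError`` so callers can catch the whole family.
"""


class ChronoqError(Exception):
    """Base class for all chronoq errors."""


class FormatError(ChronoqError, ValueError):
    """A file or table does not follow the expected layout."""


class InputError(ChronoqError, ValueError):
    """Input is syntactically fine but violates a precondition."""
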