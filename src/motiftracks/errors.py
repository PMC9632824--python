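"""Exception and warning types shared across the package."""


class MemeFormatError(ValueError):
    """A MEME results file is malformed or missing a required section."""


class UnsupportedDialectError(MemeFormatError):
    """The file is a MEME results file, but from an unsupported major version."""


class NewickParseError(ValueError):
    """A Newick string is syntactically invalid.

    Attributes
    ----------
    offset : int or None
        0-based character offset of the first offending character, when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class UnknownMotifWarning(UserWarning):
    """A requested motif id selects nothing."""


class IntersectionWarning(UserWarning):
    """A name is present on only one side of a table/tree (or table/row-order) join."""


class PpmConsistencyWarning(UserWarning):
    """A printed probability matrix disagrees with the one tallied from sites."""
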