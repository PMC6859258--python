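"""Exception hierarchy.

Every error raised on bad user input derives from :class:`GlycorankError`
so the CLI can map them to a nonzero exit with a one-line reason.
"""


class GlycorankError(Exception):
    """Base class for all input/validation failures."""


class ValidationError(GlycorankError):
    """Structurally invalid ontology, corpus, or configuration."""


class LookupError_(GlycorankError, KeyError):
    """An identifier was not found where the contract requires it."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)
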