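"""Exception hierarchy shared across the package."""


class LimnoecolError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LimnoecolError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidGateError(LimnoecolError, ValueError):
    """A flow-cytometry gate specification is malformed."""


class MismatchError(LimnoecolError, ValueError):
    """Inputs that must describe the same samples/taxa disagree."""


class TreeError(LimnoecolError, ValueError):
    """A phylogeny violates a structural precondition."""


class ParseError(LimnoecolError, ValueError):
    """A text input could not be parsed; carries position context."""


class UndefinedDiversityError(LimnoecolError, ValueError):
    """Diversity requested for an empty (all-zero) community."""
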