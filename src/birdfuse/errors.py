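"""Exception hierarchy shared across the pipeline."""


class BirdfuseError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(BirdfuseError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(BirdfuseError, ValueError):
    """A runtime input violates an operation's precondition."""


class FormatError(BirdfuseError, ValueError):
    """A file is not in the expected on-disk format."""


class SchemaError(BirdfuseError, KeyError):
    """A table/manifest is missing a required column or feature."""


class ShapeError(BirdfuseError, ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class ModelIOError(BirdfuseError, ValueError):
    """A model archive cannot be loaded (version/kind/integrity)."""
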