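"""Exception hierarchy shared across the package."""


class StarmodError(Exception):
    """Base class for all starmod errors."""


class SchemaError(StarmodError):
    """A file does not conform to its documented schema (e.g. missing column)."""


class ConfigurationError(StarmodError):
    """A scoring table, lexicon or rule set violates its invariants, or a
    product cannot be resolved against the shipped configuration."""


class InputError(StarmodError, ValueError):
    """A value passed to an operation violates its preconditions."""
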