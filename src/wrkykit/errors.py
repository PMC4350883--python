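"""Exception hierarchy shared across the package.

All errors derive from :class:`WrkyError` so callers can catch the package's
failures with a single except clause; the subclasses mirror the contract
language used throughout the API (format violations, precondition breaches,
degenerate numerical inputs).
"""


class WrkyError(Exception):
    """Base class for all wrkykit errors."""


class EmptyInput(WrkyError):
    """An input file or collection contained no records."""


class FormatError(WrkyError):
    """A file violated its declared format (ragged alignment, bad GFF3 row...)."""


class PreconditionError(WrkyError):
    """An API contract was violated by the caller."""


class DomainError(WrkyError):
    """A numeric argument fell outside the mathematical domain of an operation."""


class DegenerateDistance(WrkyError):
    """A sequence pair shared no comparable alignment columns."""

    def __init__(self, id_a: str, id_b: str):
        self.pair = (id_a, id_b)
        super().__init__(
            f"no comparable sites between {id_a!r} and {id_b!r}; "
            "p-distance is undefined for this pair"
        )


class ConfigError(WrkyError):
    """A pipeline run configuration is invalid or references missing inputs."""
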