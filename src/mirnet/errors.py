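"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3.
"""


class MirnetError(Exception):
    """Base class for all mirnet errors."""


class ConfigError(MirnetError):
    """Invalid configuration or infeasible request."""


class DataError(MirnetError):
    """Malformed or inconsistent input data."""


class UnknownIdentifierError(DataError):
    """An identifier was referenced that is not defined where it must be."""

    def __init__(self, identifier: str, context: str = ""):
        self.identifier = identifier
        msg = f"unknown identifier {identifier!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)
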