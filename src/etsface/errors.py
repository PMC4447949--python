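"""Exception hierarchy."""


class EtsfaceError(Exception):
    """Base class for all package errors."""


class ParseError(EtsfaceError):
    """A coordinate file could not be read."""


class EmptyStructureError(ParseError):
    """A file parsed syntactically but contained zero atoms."""


class SelectionError(EtsfaceError):
    """Malformed selection expression; carries the token position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at token position {position})"
        super().__init__(message)


class GeometryError(EtsfaceError):
    """Degenerate or insufficient geometry for an operation."""


class ConflictError(EtsfaceError):
    """Mutually unsatisfiable planted geometry in a synthetic build."""


class FitError(EtsfaceError):
    """Invalid input to the binding-model fitter."""
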