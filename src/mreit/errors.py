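"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: validation errors -> 2, solver
failures -> 3, quality-gate refusals -> 4.
"""


class MreitError(Exception):
    """Base class for all package errors."""


class ValidationError(MreitError, ValueError):
    """Bad user input: parameters, shapes, config keys."""


class MeshError(MreitError):
    """Degenerate or inconsistent triangulation."""


class SolverError(MreitError):
    """Linear solver failed to converge; carries a residual report."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class QualityError(MreitError):
    """Data failed a quality gate (residue density, z-continuity, ...)."""
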