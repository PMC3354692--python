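"""Exception types shared across the package."""


class TrabfeError(Exception):
    """Base class for package errors."""


class StackStructureError(TrabfeError, ValueError):
    """Slice stack is structurally inconsistent (shapes, ordering, binarity)."""


class ConfigurationError(TrabfeError, ValueError):
    """Missing or invalid metadata / pipeline configuration."""


class MeshStructureError(TrabfeError, ValueError):
    """Mesh lacks a required feature (e.g. nodes on a loading face)."""


class SolverError(TrabfeError, RuntimeError):
    """Linear solver failed to converge within its iteration cap."""

    def __init__(self, message: str, iterations: int | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


class AnalysisError(TrabfeError, ValueError):
    """Analysis stage cannot proceed (e.g. zero basic modulus)."""
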