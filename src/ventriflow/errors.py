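"""Exception types raised across the package."""


class VentriflowError(Exception):
    """Base class for all package errors."""


class GeometryInfeasibleError(VentriflowError):
    """Requested shape parameters cannot realize the requested volume range."""


class OpenSurfaceError(VentriflowError):
    """A volume was requested for a surface that cannot be closed consistently."""


class LayoutError(VentriflowError):
    """Domain pieces overlap or cannot be assembled (e.g. orifices collide)."""


class MeshImportError(VentriflowError):
    """A surface file could not be imported (empty, non-manifold, multi-component)."""


class WatertightnessError(VentriflowError):
    """The immersed geometry leaks: exterior connects to the cavity interior."""


class StepSizeError(VentriflowError):
    """Time step violates the CFL constraint."""


class SolverDivergenceError(VentriflowError):
    """NaN/Inf detected in the flow state."""


class PhaseError(VentriflowError):
    """An operation was requested in the wrong cardiac phase or an empty phase window."""


class ConfigError(VentriflowError):
    """Invalid run configuration."""
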