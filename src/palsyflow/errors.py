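"""Exception hierarchy shared across the package."""


class PalsyflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PalsyflowError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(PalsyflowError, ValueError):
    """A file or container is malformed or internally inconsistent."""


class DegenerateGeometryError(PalsyflowError, ValueError):
    """A geometric configuration is rank-deficient (e.g. coplanar 3D points)."""


class DegenerateTrainingError(PalsyflowError, ValueError):
    """Training data cannot support the requested classifier (e.g. one class)."""
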