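"""Exception hierarchy shared across the package."""


class ProjectomeError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(ProjectomeError):
    """An input file violates its documented schema (names the offending record)."""


class ValidationError(ProjectomeError):
    """A value fails a domain invariant (non-negative counts, labels, ranges)."""


class StructuralError(ProjectomeError):
    """A reconstruction tree is not a rooted tree (cycle, dangling parent, unreachable node)."""


class NullModelUndefinedError(ProjectomeError):
    """The swap-randomization null requires at least two neurons and two regions."""


class DegenerateGeometryError(ProjectomeError):
    """A point set does not span a 3D convex hull."""


class UndefinedCompositionError(ProjectomeError):
    """Afferent composition requested for a region no class projects to."""
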