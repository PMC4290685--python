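"""Exception hierarchy for patchkernel.

All package-specific failures derive from :class:`PatchKernelError` so callers
can catch one base class; subclasses also derive from the closest builtin
(ValueError / RuntimeError) to stay idiomatic.
"""


class PatchKernelError(Exception):
    """Base class for all patchkernel errors."""


class FormatError(PatchKernelError, ValueError):
    """An input file does not follow its documented format."""


class EmptyInputError(PatchKernelError, ValueError):
    """An input that must be non-empty (e.g. a structure with residues) is empty."""


class DataError(PatchKernelError, ValueError):
    """A residue is missing data required by the requested operation."""


class StateError(PatchKernelError, RuntimeError):
    """An object is used before it reached the required state (e.g. unnormalized)."""


class EmptyInterfaceError(PatchKernelError, ValueError):
    """A protein has no interface residues, so no interface patch exists."""


class DimensionError(PatchKernelError, ValueError):
    """Vector lengths disagree."""


class SamplingError(PatchKernelError, RuntimeError):
    """Randomized patch sampling failed after bounded restarts."""


class GenerationError(PatchKernelError, RuntimeError):
    """Synthetic structure generation failed after bounded restarts."""
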