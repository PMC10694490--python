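"""Exception hierarchy shared across the package.

Separating usage errors (bad arguments) from data/format errors (bad files,
inconsistent inputs) lets the CLI map them onto distinct exit codes.
"""


class PhylobinError(Exception):
    """Base class for all package-specific errors."""


class UsageError(PhylobinError):
    """Caller supplied invalid arguments (empty set, bad threshold, ...)."""


class FormatError(PhylobinError):
    """A file or text blob does not conform to its declared format."""


class ConsistencyError(PhylobinError):
    """Inputs are individually valid but mutually inconsistent
    (e.g. a placement referencing an edge absent from the tree)."""


class CompatibilityError(PhylobinError):
    """Artifacts built against different reference trees were combined."""


class GenerationError(PhylobinError):
    """The synthetic generator could not satisfy the requested constraints."""
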