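"""Exception types shared across the package."""


class HsipathError(Exception):
    """Base class for all package errors."""


class FormatError(HsipathError):
    """An on-disk cube or header is malformed or self-contradictory."""


class ValidationError(HsipathError):
    """An in-memory object violates its invariants (manifest, cube, plan)."""


class InfeasibleError(HsipathError):
    """A requested partition or design cannot satisfy its constraints."""
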