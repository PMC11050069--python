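"""Named exception types raised across the pipeline.

Every reader and every stage rejects malformed input with one of these,
never with silent coercion.
"""


class PloidyConsensusError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PloidyConsensusError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(PloidyConsensusError):
    """An in-memory object violates its invariants (bad config, bad matrix)."""


class DomainError(PloidyConsensusError):
    """A numeric routine was called with out-of-domain parameters."""
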