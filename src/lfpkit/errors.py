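"""Exception hierarchy shared across lfpkit modules."""


class LfpkitError(Exception):
    """Base class for all lfpkit errors."""


class ConfigError(LfpkitError, ValueError):
    """Session config file is missing fields or fails validation."""


class FormatError(LfpkitError, ValueError):
    """A binary file does not match the expected on-disk layout."""


class ManifestError(LfpkitError, ValueError):
    """Session directory contents are inconsistent (orphan files, etc.)."""


class SyncError(LfpkitError, ValueError):
    """Timestamp/frame stream violates a synchronization invariant."""


class ParameterError(LfpkitError, ValueError):
    """Invalid analysis parameter combination."""


class ValidationError(LfpkitError, ValueError):
    """A domain object violates one of its invariants."""
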