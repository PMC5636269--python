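"""Exception types shared across the package."""


class TmesimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TmesimError):
    """A run configuration violates an invariant (bad lattice, probability, range)."""


class IntegrityError(TmesimError):
    """Simulation state is internally inconsistent; never silently repaired."""


class SnapshotError(TmesimError):
    """A snapshot file is unreadable, truncated or has an incompatible schema."""
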