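"""Exception hierarchy shared across the package."""


class MeakitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MeakitError):
    """A configuration file or metadata record is missing a required field."""


class MalformedFileError(MeakitError):
    """A data file is structurally inconsistent with its declared metadata."""


class SchemaError(MeakitError):
    """An HDF5/CSV container carries an unknown or missing schema tag."""


class ParameterError(MeakitError, ValueError):
    """A parameter violates its documented invariant."""


class InputError(MeakitError, ValueError):
    """An input object violates a precondition of an operation."""


class AlignmentError(MeakitError):
    """Edge alignment failed because a series never crosses its edge level."""
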