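"""Exception hierarchy shared across the ETL pipeline.

Every error raised deliberately by this package derives from :class:`PdmsEtlError`
so callers can distinguish pipeline failures from programming errors.
"""


class PdmsEtlError(Exception):
    """Base class for all errors raised by pdms_etl."""


class ConfigurationError(PdmsEtlError):
    """Invalid or missing configuration (bad synthetic config, malformed contract, absent salt)."""


class SourceConnectionError(PdmsEtlError):
    """The relational source could not be reached or opened."""


class ReadOnlyViolationError(PdmsEtlError):
    """A statement attempted to mutate the read-only source."""


class SchemaError(PdmsEtlError):
    """A referenced table or column does not exist in the source."""


class TimestampFormatError(PdmsEtlError):
    """A timestamp string could not be parsed as an ISO-8601 UTC instant."""


class DimensionError(PdmsEtlError):
    """A unit conversion was requested across incompatible dimensions."""


class UnknownUnitError(PdmsEtlError):
    """A unit symbol is not present in the unit registry."""


class CatalogError(PdmsEtlError):
    """A drug or variable identifier could not be resolved against its catalog."""


class UnresolvableRecordError(PdmsEtlError):
    """A medication record cannot be standardized (e.g. volume dose without an interval)."""


class GroupingError(PdmsEtlError):
    """Records from mixed (case, device) groups were passed to a single-group operation."""


class RegistrationError(PdmsEtlError):
    """A resource name is already registered."""


class ResourceLookupError(PdmsEtlError):
    """A resource or template name is not registered."""


class AuthorizationError(PdmsEtlError):
    """The acting user is not permitted to run the requested template."""


class ExportError(PdmsEtlError):
    """An export artifact could not be written."""
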