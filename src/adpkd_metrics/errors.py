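"""Exception hierarchy.

All package errors derive from :class:`AdpkdMetricsError` so callers can
catch everything from one root; the leaves distinguish malformed files from
bad geometry, registry mismatches, and statistically unusable inputs.
"""


class AdpkdMetricsError(Exception):
    """Root of the package's exception hierarchy."""


class FormatError(AdpkdMetricsError):
    """A file on disk is not a readable volume (bad header, bad spacing)."""


class RegistryError(AdpkdMetricsError):
    """A label code is missing from, or inconsistent with, the registry."""


class InputError(AdpkdMetricsError, ValueError):
    """An argument violates a precondition (negative volume, zero height...)."""


class GeometryError(AdpkdMetricsError):
    """Grids do not match, or a primitive does not fit the grid."""


class CoverageGapError(AdpkdMetricsError):
    """Stacked series leave a gap larger than one slice thickness."""


class TagError(AdpkdMetricsError):
    """Composite-series images are missing the discriminating echo/b tag."""


class TimeParseError(AdpkdMetricsError, ValueError):
    """A DICOM time string does not conform to HHMMSS[.frac]."""


class PhantomSpecError(AdpkdMetricsError):
    """A phantom specification is internally inconsistent."""


class EmptyStructureError(AdpkdMetricsError):
    """An operation that needs a non-empty mask received an empty one."""


class EligibilityError(AdpkdMetricsError):
    """No measurement survives the sequence-class eligibility filter."""


class SpanError(AdpkdMetricsError):
    """Longitudinal observations span less than the required interval."""


class ConsistencyError(AdpkdMetricsError):
    """Derived quantities contradict each other (cysts exceed liver...)."""


class SignalError(AdpkdMetricsError):
    """Intensity data unusable inside the requested mask."""
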