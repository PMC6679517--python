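"""Exception hierarchy for gaitcsm.

All errors derive from :class:`GaitCSMError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the pipeline stages.
"""


class GaitCSMError(Exception):
    """Base class for all gaitcsm errors."""


class ConfigurationError(GaitCSMError, ValueError):
    """Invalid generator / training / run configuration."""


class FormatError(GaitCSMError, ValueError):
    """Malformed input file (CSV / JSON)."""


class DegenerateSignalError(GaitCSMError, ValueError):
    """Signal too flat or too short for threshold estimation."""


class LabelingError(GaitCSMError, ValueError):
    """Four-phase labeling failed (e.g. transition windows overlap)."""


class ModelValidityError(GaitCSMError, ValueError):
    """Template or model violates its invariants (delta <= 0, wrong length...)."""


class TrainingDataError(GaitCSMError, ValueError):
    """Labeled training data contains no usable transitions."""


class UndefinedRateError(GaitCSMError, ZeroDivisionError):
    """An error rate is undefined because the true phase count is zero."""


class ConfigurationWarning(UserWarning):
    """Non-fatal configuration issue (e.g. epsilon outside the preferred bound)."""
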