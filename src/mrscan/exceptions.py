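"""Exception hierarchy for mrscan."""


class MRScanError(Exception):
    """Base class for all mrscan errors."""


class ConfigurationError(MRScanError, ValueError):
    """Invalid configuration: bad column map, negative threshold, unknown method."""


class EmptyDatasetError(MRScanError, ValueError):
    """A summary-statistic table yielded zero valid records."""


class DomainError(MRScanError, ValueError):
    """A numeric argument is outside the domain of a formula (e.g. R2 >= 1)."""


class DegenerateInstrumentError(MRScanError, ValueError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


class WrongMethodError(MRScanError, ValueError):
    """An estimator was called with an instrument count it does not support."""


class HarmonizationError(MRScanError, ValueError):
    """Records handed to harmonization do not refer to the same genomic position."""
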