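"""Exception types raised by dnmkit operations."""


class DnmkitError(ValueError):
    """Base class for all dnmkit input/processing errors."""


class ClassificationError(DnmkitError):
    """A mutation record cannot be assigned a functional class."""


class FilterError(DnmkitError):
    """A filter criterion references a field that is missing on a record."""


class CalibrationError(DnmkitError):
    """Synonymous-rate calibration is undefined (zero case synonymous count)."""
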