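"""Exception types."""


class RingmotionError(Exception):
    """Base class for package errors."""


class FormatError(RingmotionError, ValueError):
    """Malformed input file (missing columns, gaps, inconsistent spacing)."""


class DegenerateDataError(RingmotionError, ValueError):
    """The data cannot support the requested estimate (e.g. no events observed,
    or an emission variance collapsing to zero)."""
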