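"""Exception types shared across the pipeline."""


class GeometryError(ValueError):
    """A stimulus element does not fit on the screen."""


class ConfigurationError(ValueError):
    """A run/simulation configuration is inconsistent or incomplete."""


class DataError(ValueError):
    """Input data violate a contract (e.g. non-positive fluorescence)."""


class AlignmentError(ValueError):
    """Traces that must share a time base do not."""


class DegenerateResponseError(ValueError):
    """A response has no usable structure (zero kernel, non-positive peak)."""
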