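"""Exception hierarchy for cardiotel."""


class CardiotelError(Exception):
    """Base class for all cardiotel errors."""


class ConfigError(CardiotelError):
    """Invalid simulation or pipeline configuration."""


class RenderError(CardiotelError):
    """Waveform rendering is impossible (e.g. pulse shorter than 2 samples)."""


class NoBeatsError(CardiotelError):
    """No beats could be detected (flat or non-finite signal)."""


class SignalQualityError(CardiotelError):
    """Signal fails quality screens (e.g. saturation at the rails)."""


class SegmentSelectionError(CardiotelError):
    """No window satisfies the spectral segment-selection criteria."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


class ParseError(CardiotelError):
    """Malformed input file."""


class AnalysisError(CardiotelError):
    """An analysis precondition is violated."""
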