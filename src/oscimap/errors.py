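"""Exception types shared across the oscimap pipeline."""


class OscimapError(RuntimeError):
    """Base class for pipeline failures."""


class SignalError(OscimapError):
    """Raised when a cuff recording cannot be decomposed (too short,
    non-finite samples, too few pulses)."""


class EnvelopeError(OscimapError):
    """Raised when an envelope cannot support a requested operation
    (amplitude above the maximum, branch never reaching the target,
    reference pressure outside the envelope's support)."""


class GridError(OscimapError):
    """Raised for ill-formed candidate-ratio grids."""


class TruthError(OscimapError):
    """Raised when synthetic ground-truth parameters are geometrically
    inconsistent (no envelope can satisfy them)."""
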