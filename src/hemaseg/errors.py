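"""Shared exception types."""


class ConfigurationError(ValueError):
    """Invalid configuration value (bounds, fractions, windows...)."""


class PlacementError(RuntimeError):
    """A tumor could not be placed inside the field of view."""


class EmptyMaskError(ValueError):
    """A tumor mask is empty at the requested resolution.

    Callers that hit this at inference time should fall back to
    population-level Gaussian statistics.
    """


class ShapeMismatchError(ValueError):
    """Arrays that must be aligned have inconsistent shapes."""
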