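"""Exception hierarchy shared across the package."""


class OcuScreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OcuScreenError, ValueError):
    """Invalid configuration, layout, or input data."""


class PlacementError(OcuScreenError, RuntimeError):
    """Synthetic cells could not be placed without overlap."""


class SeparationError(OcuScreenError, RuntimeError):
    """Logistic fit is not identifiable (complete/quasi-complete separation)."""


class FitError(OcuScreenError, RuntimeError):
    """A fitted-model operation is undefined or unavailable."""


class PipelineError(OcuScreenError, RuntimeError):
    """A pipeline stage failed; message carries the stage name and context."""
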