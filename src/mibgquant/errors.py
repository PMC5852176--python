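"""Exception hierarchy shared across the package."""


class MibgError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MibgError, ValueError):
    """An input value violates a contract (non-positive coefficient, negative interval, ...)."""


class ConfigurationError(MibgError, KeyError):
    """A referenced collimator or configuration entry is missing or malformed."""


class PlacementError(MibgError, ValueError):
    """ROI geometry cannot be placed inside the image frame."""


class DegenerateInputError(MibgError, ValueError):
    """Input is formally valid but degenerate for the requested computation
    (zero mediastinal counts, no myocardial signal above background, ...)."""
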