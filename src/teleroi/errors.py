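"""Exception hierarchy for scenario loading and evaluation."""

from __future__ import annotations


class TeleroiError(Exception):
    """Base class for all package-specific errors."""


class ScenarioValidationError(TeleroiError):
    """A scenario document violates the schema or a domain invariant.

    ``path`` anchors the offending entry inside the document
    (e.g. ``care_models[1].staff_lines[0].site_id``).
    """

    def __init__(self, message: str, path: str | None = None):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


class UnknownSiteError(TeleroiError):
    """A site id was referenced that the care model does not declare."""


class MissingRateError(TeleroiError):
    """A funding stream has no rate for a referenced financial year."""


class MissingYearError(TeleroiError):
    """A discount schedule has no factor for a referenced financial year."""
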