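"""Exception hierarchy for panel validation and inference failures."""


class PanelError(ValueError):
    """Base class for panel-data validation and domain errors."""


class UnbalancedPanelError(PanelError):
    """Raised when a panel is missing (unit, year) cells.

    The offending pairs are available on the ``pairs`` attribute.
    """

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"({u!r}, {y})" for u, y in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" (+{len(self.pairs) - 10} more)"
        super().__init__(f"unbalanced panel: missing cells {shown}{more}")


class DuplicateRecordError(PanelError):
    """Raised when the same (unit, year) appears more than once."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"({u!r}, {y})" for u, y in self.pairs[:10])
        super().__init__(f"duplicate (unit, year) records: {shown}")


class NonPositiveValueError(PanelError):
    """Raised when a density value is zero or negative (logs/transition paths undefined)."""

    def __init__(self, unit, year, value):
        self.unit, self.year, self.value = unit, year, value
        super().__init__(
            f"non-positive value {value!r} at unit {unit!r}, year {year}: "
            "densities must be strictly positive"
        )


class DegenerateCrossSectionError(PanelError):
    """Raised when a cross-sectional mean is <= 0 so relative transitions are undefined."""

    def __init__(self, t_index, mean):
        self.t_index, self.mean = t_index, mean
        super().__init__(
            f"cross-sectional mean {mean:.6g} <= 0 at time index {t_index}; "
            "relative transition paths undefined (rescale units so all logs are positive)"
        )


class InsufficientSampleError(PanelError):
    """Raised when a series or panel is too short for the requested operation."""
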