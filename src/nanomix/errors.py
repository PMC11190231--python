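"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ComponentCollapseError(RuntimeError):
    """A mixture component lost all posterior mass during EM.

    Raised when a responsibility column sums to (numerically) zero, which
    happens when an initialization strands a component far from the data or
    when K exceeds the number of resolvable sub-populations.
    """

    def __init__(self, component: int, column_sum: float):
        self.component = component
        self.column_sum = column_sum
        super().__init__(
            f"component {component} collapsed (responsibility mass "
            f"{column_sum:.3e}); try a different initialization or smaller K"
        )
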