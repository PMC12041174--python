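"""Exception hierarchy for the arterial-network model.

Error message prefixes (``no_open_path``, ``nonphysical_baseline``,
``infeasible_targets``, ``generation_failed``) are stable identifiers that
callers may match on.
"""


class HepanetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HepanetError):
    """A serialised network/config violates the documented schema.

    The message names the offending field path.
    """


class NetworkValidationError(HepanetError):
    """A network failed structural validation; carries the diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__("invalid network: " + "; ".join(self.diagnostics))


class NoOpenPathError(HepanetError):
    """No unclamped path connects the pressure inlet to any outlet."""

    def __init__(self, detail: str = ""):
        super().__init__(f"no_open_path{': ' + detail if detail else ''}")


class NonphysicalBaselineError(HepanetError):
    """Baseline GDA flow exceeds CHA flow under antegrade (Michels I) anatomy.

    Suggests celiac-trunk stenosis with collateral reversal; the caller
    should use the stenosis pathway instead of antegrade PHA inference.
    """

    def __init__(self, detail: str = ""):
        super().__init__(
            f"nonphysical_baseline{': ' + detail if detail else ''}"
            " (consider the CELIAC_STENOSIS variant)"
        )


class InfeasibleTargetsError(HepanetError):
    """Measured target flows cannot be reached under the fixed inlet pressure."""

    def __init__(self, detail: str = ""):
        super().__init__(f"infeasible_targets{': ' + detail if detail else ''}")


class GenerationFailedError(HepanetError):
    """Synthetic-patient rejection sampling exhausted its retry budget."""

    def __init__(self, seed: int, detail: str = ""):
        self.seed = seed
        super().__init__(
            f"generation_failed: seed={seed}{' ' + detail if detail else ''}"
        )
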