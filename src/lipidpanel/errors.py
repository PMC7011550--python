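"""Exception hierarchy for lipidpanel."""


class LipidPanelError(Exception):
    """Base class for all lipidpanel errors."""


class PanelConfigError(LipidPanelError):
    """Invalid or unreadable panel configuration."""


class UnknownPhenotypeError(LipidPanelError):
    """A phenotype key not known to the panel was requested."""

    def __init__(self, phenotype, valid_keys):
        self.phenotype = phenotype
        self.valid_keys = sorted(valid_keys)
        super().__init__(
            f"unknown phenotype {phenotype!r}; valid keys: {', '.join(self.valid_keys)}"
        )


class VariantInputError(LipidPanelError):
    """Malformed variant or annotation input."""


class CnvCallingError(LipidPanelError):
    """Invalid input to the CNV caller."""


class ScoreError(LipidPanelError):
    """Invalid polygenic-score input."""


class ProfileError(LipidPanelError):
    """Invalid input to genetic profiling."""
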