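"""Exception hierarchy shared across the package."""


class OncoPanelError(Exception):
    """Base class for all package errors."""


class FormatError(OncoPanelError):
    """Malformed or unreadable input data (exit code 2 on the CLI)."""


class ConfigError(OncoPanelError):
    """Invalid configuration or argument combination."""


class MissingModelError(OncoPanelError):
    """A gene requires whole-exome representation but has no exon model."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(
            f"gene {gene_id!r} requires whole-exome inclusion but has no exon model"
        )


class EmptyPanelError(OncoPanelError):
    """No listed gene carries a protein-affecting mutation in the cohort."""
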