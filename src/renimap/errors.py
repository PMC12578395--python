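"""Exception types shared across the pipeline."""


class RenimapError(Exception):
    """Base class for pipeline errors."""


class ConfigError(RenimapError):
    """A configuration object (panel, gating tree, rates) is inconsistent."""


class PlacementError(RenimapError):
    """A synthetic structure could not be placed in the requested field."""

    def __init__(self, structure: str, message: str = ""):
        self.structure = structure
        super().__init__(message or f"could not place structure: {structure}")
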