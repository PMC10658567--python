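"""Exception hierarchy shared across the package."""


class EpimapError(Exception):
    """Base class for all epimap errors."""


class InvalidArgumentError(EpimapError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(EpimapError, ValueError):
    """A parameter combination is internally inconsistent (e.g. band edge
    above Nyquist, grid adjacency requested without grid indices)."""


class InvalidScenarioError(EpimapError, ValueError):
    """A propagation scenario is self-contradictory (e.g. a source placed
    on a non-conducting lesion electrode)."""


class MeshParseError(EpimapError, ValueError):
    """A surface-mesh file could not be parsed."""
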