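"""Exception hierarchy for the mlsm package."""


class MlsmError(Exception):
    """Base class for all mlsm errors."""


class VolumeFormatError(MlsmError):
    """A volume file is unreadable or has the wrong dimensionality."""


class GridMismatchError(MlsmError):
    """Two volumes that must share a voxel grid do not."""


class ContractError(MlsmError):
    """An input violates a documented precondition (e.g. non-binary mask)."""


class FeaturizationError(MlsmError):
    """Feature assembly failed (grid mismatch, empty case set, missing data)."""


class EvaluationError(MlsmError):
    """Cross-validated evaluation cannot be performed (too few cases, constant response)."""


class MappingError(MlsmError):
    """Model columns cannot be mapped onto atlas ROIs."""


class GenerationError(MlsmError):
    """Synthetic data generation failed (infeasible target, exhausted retries)."""


class ConfigError(MlsmError):
    """A run configuration is invalid (unknown key, bad vocabulary value, missing path)."""
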