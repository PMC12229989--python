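"""Exception hierarchy for hypermhc.

Exit-code mapping used by the CLI: ConfigError -> 1, data-validation
errors -> 2, everything else -> 3.
"""


class HyperMHCError(Exception):
    """Base class for all package errors."""


class ConfigError(HyperMHCError):
    """Invalid or unknown configuration keys/values."""


class DataError(HyperMHCError):
    """Base class for data-validation failures."""


class InvalidAffinity(DataError):
    """Affinity is non-positive or non-finite."""


class InvalidScore(DataError):
    """Normalized score outside [0, 1]."""


class InvalidSequence(DataError):
    """Sequence contains non-canonical residue characters."""


class UnknownAllele(DataError):
    """Allele name does not resolve in the allele table."""


class MissingFolds(DataError):
    """Cross-validation requested but fold ids are absent."""


class BackendError(HyperMHCError):
    """Embedding backend unavailable or failed."""


class EmptyBatch(DataError):
    """Loss requested on an empty batch."""


class EmptyTrainingSet(DataError):
    """No usable records survive validation/rejection."""


class ShapeError(DataError):
    """Array shapes do not agree with the declared contract."""


class AsymmetricMap(DataError):
    """Contact map is not symmetric within tolerance."""


class TooShort(DataError):
    """Sequence/map too short for the requested operation."""


class RecordRejected(DataError):
    """Hypergraph has no hyperedge with >= 2 members; pair is discarded."""


class PeptideTooShort(DataError):
    """Peptide shorter than the core-detection window."""


class InvalidMap(DataError):
    """Matrix contains non-finite entries."""


class DegenerateLabels(DataError):
    """Metric needs both classes / at least one positive."""


class DegenerateInput(DataError):
    """Metric input is constant or too short."""


class NotEnoughAlleles(DataError):
    """Fewer than two alleles pass the LOMO filter."""


class SimError(HyperMHCError):
    """Infeasible synthetic-data configuration."""
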