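"""Exception hierarchy for bactsig."""


class BactsigError(Exception):
    """Base class for all bactsig errors."""


class ConfigurationError(BactsigError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(BactsigError):
    """The requested synthetic dataset cannot be generated (e.g. a mutation
    channel has no matching context anywhere in the genome)."""


class FormatError(BactsigError):
    """A file does not conform to its expected format (VCF/GFF3/COSMIC TSV/GMT)."""


class ReferenceMismatchError(BactsigError):
    """A variant's REF allele disagrees with the reference genome."""


class ClassificationError(BactsigError):
    """A variant cannot be assigned a trinucleotide channel (e.g. terminal position)."""


class ChannelAlignmentError(BactsigError):
    """Two channel-indexed objects do not share the same channel order."""


class NormalizationError(BactsigError):
    """Trinucleotide-frequency renormalization is undefined for some context."""
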