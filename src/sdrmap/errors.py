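"""Exception types shared across the pipeline."""


class SdrmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SdrmapError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class GenotypeParseError(SdrmapError, ValueError):
    """A genotype/count/map file could not be parsed; message names row/column."""


class ReferenceError_(SdrmapError, KeyError):
    """An identifier refers to an entity absent from its reference table."""


class UnphaseableFamilyError(SdrmapError):
    """No paternally informative marker: parental haplotypes cannot be phased."""


class ConsensusUndefinedError(SdrmapError):
    """A family lacks phenotyped individuals of one sex, so no per-sex
    consensus genotype can be formed."""


class InconsistentEventsError(SdrmapError):
    """Recombination events leave no interval consistent with every
    individual's sex (suggests a phenotype or genotype error)."""
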