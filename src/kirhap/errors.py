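"""Exception hierarchy for kirhap."""


class KirhapError(Exception):
    """Base class for all kirhap errors."""


class GrammarError(KirhapError):
    """A haplotype name, motif or submotif combination violates the
    gene-content grammar (ordering, applicability, framework or copy bounds)."""


class ParseError(KirhapError):
    """A packaged or user-supplied table failed to parse."""


class CoverageError(KirhapError):
    """An assay table leaves a locus with fewer than the required number of
    independent confirmations."""


class NoSignalError(KirhapError):
    """All peak heights at a scored position are below the detection floor
    (every assay is expected to yield product)."""


class UnresolvableGenotypeError(KirhapError):
    """No copy-number vector satisfies the concordant assay constraints."""

    def __init__(self, message, constraints=None):
        super().__init__(message)
        self.constraints = constraints or []


class AnalysisError(KirhapError):
    """A downstream analysis (EM, LD, scan) could not be carried out."""
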