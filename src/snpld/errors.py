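"""Exception hierarchy shared across the package."""


class SnpldError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SnpldError):
    """Malformed PED/MAP/population-map input."""


class NonBiallelicError(FormatError):
    """More than two distinct non-missing allele codes observed at a locus."""

    def __init__(self, vid: str, alleles):
        self.vid = vid
        self.alleles = sorted(alleles)
        super().__init__(
            f"locus {vid!r} has more than two non-missing allele codes: {self.alleles}"
        )


class UndefinedStatisticError(SnpldError):
    """A statistic has no defined value for the given input (e.g. MAF of an
    all-missing column, Q when chance agreement is 1)."""


class MonomorphicPairError(SnpldError):
    """At least one locus of a pair is monomorphic in the analysed samples, so
    D', r2 and haplotype-frequency estimation are undefined."""


class InsufficientDataError(SnpldError):
    """Fewer than two pairwise-complete individuals for a locus pair."""


class InfeasibleConfigError(SnpldError):
    """A simulation configuration that cannot be realised as specified."""
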