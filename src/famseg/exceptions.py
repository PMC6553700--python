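"""Exception and warning types shared across the package."""


class FamsegError(Exception):
    """Base class for all errors raised by famseg."""


class PedigreeStructureError(FamsegError):
    """The pedigree graph is malformed (cycle, bad parent sex, ...)."""


class DuplicateIndividualError(FamsegError):
    """The same individual id occurs twice within one family."""


class UnknownIndividualError(FamsegError, KeyError):
    """An individual id was looked up that is not in the pedigree."""


class MendelianInconsistencyError(FamsegError):
    """Observed genotype calls are jointly impossible under Mendelian
    transmission with no de novo events (e.g. a carrier child of two
    observed wild-type parents)."""


class InsufficientDataError(FamsegError):
    """Too few informative individuals/calls to run the requested analysis."""


class AnnotationError(FamsegError):
    """A VCF record lacks the required consequence annotation."""


class UndefinedEffectError(FamsegError):
    """An odds ratio is undefined (no carriers in either group)."""


class InconclusiveHaplotypeError(FamsegError):
    """Too few co-genotyped markers to call shared vs independent origin.

    Deliberately an error, not a third verdict: callers must handle it
    explicitly rather than treat it as evidence either way.
    """


class SingleOriginViolationWarning(UserWarning):
    """Observed carriers cannot all descend from one founder introduction."""


class HomozygousGenotypeWarning(UserWarning):
    """A homozygous-alternate genotype was collapsed to 'carrier'."""
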