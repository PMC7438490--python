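"""Exception hierarchy for pedigree parsing, validation and likelihood evaluation."""


class CosegError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(CosegError, ValueError):
    """Base class for pedigree file / structure errors."""


class DuplicateIdError(PedigreeError):
    """An individual id occurs more than once within a family."""


class UnmatchedIdError(PedigreeError):
    """A parent or phenotype row references an id absent from the family."""


class PedigreeLoopError(PedigreeError):
    """The relationship graph (individuals + matings) contains a cycle."""


class ProbandError(PedigreeError):
    """Proband missing, duplicated, or genotyped as a non-carrier."""


class PedigreeValidationError(PedigreeError):
    """A loaded pedigree breaches a data-model invariant (carries findings)."""

    def __init__(self, findings):
        self.findings = list(findings)
        msg = "; ".join(str(f) for f in self.findings)
        super().__init__(f"pedigree validation failed: {msg}")


class PenetranceError(CosegError, ValueError):
    """Malformed penetrance table or schema violation."""


class AgeOutOfRangeError(PenetranceError):
    """Requested age lies outside the model's age grid."""


class MendelianInconsistencyError(CosegError):
    """Observed genotypes have probability zero under Mendelian transmission."""


class DuplicateFamilyError(CosegError, ValueError):
    """Likelihood-ratio combination received two results for one family."""


class EnumerationGuardError(CosegError):
    """Brute-force enumeration refused: too many untested genotypes."""


class AscertainmentError(CosegError):
    """Family simulation failed to satisfy the ascertainment rule."""


class ClassificationError(CosegError, ValueError):
    """Invalid input to the in-silico prior / posterior machinery."""
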