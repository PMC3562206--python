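"""Exception hierarchy for sibphase."""


class SibphaseError(Exception):
    """Base class for all sibphase errors."""


class FormatError(SibphaseError):
    """Malformed input file (bad allele code, wrong column count, ...)."""


class StructureError(SibphaseError):
    """Invalid pedigree structure (missing parent, cycle, half-specified parents)."""


class MapOrderError(SibphaseError):
    """Marker map positions are not nondecreasing, or multiple chromosomes."""


class UnsupportedError(SibphaseError):
    """Requested configuration outside the supported model family (e.g. k > 2)."""


class ParameterError(SibphaseError):
    """Parameter value outside its valid domain."""


class MendelianConflictError(SibphaseError):
    """Observed genotypes are impossible under the pedigree at some marker.

    Raised only when genotypes are treated as exact (error-tolerant mode off).
    """

    def __init__(self, marker_index: int, detail: str = ""):
        self.marker_index = marker_index
        msg = f"Mendelian conflict at marker index {marker_index}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
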