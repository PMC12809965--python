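"""Exception types shared across polybench modules."""


class PolybenchError(Exception):
    """Base class for all polybench errors."""


class VcfParseError(PolybenchError):
    """A VCF line could not be parsed; message names the file and line."""


class PloidyError(PolybenchError):
    """A genotype's ploidy disagrees with the declared/expected ploidy."""


class ConsistencyError(PolybenchError):
    """A record's REF allele disagrees with the reference sequence."""


class OrderingError(PolybenchError):
    """Input records are not coordinate-sorted where sorting is required."""


class ContractError(PolybenchError):
    """A precondition of an operation was violated by the caller."""
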