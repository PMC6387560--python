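"""Exception types shared across the package."""


class VihmmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VihmmError):
    """A file does not conform to its declared format."""


class ValidationError(VihmmError):
    """An in-memory object violates one of its invariants."""


class ConsistencyError(VihmmError):
    """Two inputs that must agree (e.g. VCF REF vs reference) do not."""


class RecordError(VihmmError):
    """A single record (read, VCF line) is malformed; carries its name."""


class DecodeError(VihmmError):
    """Viterbi decoding failed (e.g. no admissible state at a column)."""


class AdmissibilityError(VihmmError):
    """A state was queried in a reference context where it cannot occur."""
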