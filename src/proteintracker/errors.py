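"""Exception hierarchy shared by all proteintracker modules."""


class ProteinTrackerError(Exception):
    """Base class for all errors raised by this package."""


# --- sequence / calculation errors -----------------------------------------

class EmptySequence(ProteinTrackerError):
    """Nothing remains after normalization of a sequence string."""


class IllegalResidue(ProteinTrackerError):
    """A character outside the 20 standard one-letter amino-acid codes.

    Ambiguity codes (B, J, O, U, X, Z) are rejected rather than assigned
    zero mass: a silently wrong molecular weight would propagate into the
    A280 and mass bookkeeping of every downstream record.
    """

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based, within the normalized sequence
        super().__init__(f"illegal residue {residue!r} at position {position}")


class NegativeQuantity(ProteinTrackerError):
    """A concentration, volume or mass below zero."""


class AliquotBoundsViolation(ProteinTrackerError):
    """current_aliquots outside [0, original_aliquots] or a negative count."""


# --- store / record errors --------------------------------------------------

class PermissionDenied(ProteinTrackerError):
    """The supplied role does not permit this mutation."""


class ValidationFailed(ProteinTrackerError):
    """A record failed link/invariant validation; carries every violation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations) or "validation failed")


class NotFound(ProteinTrackerError):
    """No record with the given identifier exists in the store."""


class ReferencedRecord(ProteinTrackerError):
    """Deletion refused: a downstream record still references this one."""


class UnknownField(ProteinTrackerError):
    """A sort or filter names a field the record type does not have."""


class IOFailure(ProteinTrackerError):
    """An export could not be written."""


class BrokenLineage(ProteinTrackerError):
    """A lineage link points at a record that does not exist."""


class StoreNotEmpty(ProteinTrackerError):
    """Fixture population requires an empty store."""


# --- workflow errors ---------------------------------------------------------

class IllegalTransition(ProteinTrackerError):
    """Request status may only move Pending -> Started -> Fulfilled."""


class NotPending(ProteinTrackerError):
    """Only Pending requests can be prioritized or deleted."""


class MissingQuantity(ProteinTrackerError):
    """A transfection request needs a volume (suspension) or flask count."""


class MalformedLink(ProteinTrackerError):
    """Text is not a well-formed proteintracker:// external link."""
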