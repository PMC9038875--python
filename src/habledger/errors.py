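"""Exception hierarchy for ledger domain rules and file formats."""


class LedgerError(Exception):
    """Base class for every domain-rule violation raised by the engine."""


class UnknownEcotypeError(LedgerError):
    """An operation referenced an ecotype absent from the service area."""


class ReserveRuleError(LedgerError):
    """A trading operation touched a parcel held in the natural capital reserves."""


class RetiredParcelError(LedgerError):
    """A retired parcel was referenced by an operation that needs live habitat."""


class NonPositiveGainError(LedgerError):
    """A deposit would not realise a net PWSA gain."""


class InsufficientBalanceError(LedgerError):
    """Matured, uncommitted deposit value does not cover the requested debit."""


class DoubleOffsetError(LedgerError):
    """A withdrawal that was already traded against cannot be offset twice."""


class TransferError(LedgerError):
    """An inter-service-area transfer violated its preconditions."""


class ParcelInputError(LedgerError):
    """A parcel inventory file failed schema or content checks."""


class JournalFormatError(LedgerError):
    """A persisted journal is corrupted, mis-typed, or out of order."""


class InfeasibleParamsError(LedgerError):
    """Synthetic-fixture parameters cannot be realised."""
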