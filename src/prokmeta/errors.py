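"""Exception hierarchy shared across the package."""


class ProkmetaError(Exception):
    """Base class for all package errors."""


class InputError(ProkmetaError):
    """The input source could not be read at all (missing file, I/O failure).

    Distinct from :class:`ReportParseError`, which means the source was
    readable but its content violated the dialect in strict mode.
    """


class ReportParseError(ProkmetaError):
    """Strict-mode parse failure; carries the offending 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class SchemaError(ProkmetaError):
    """A curated CSV does not carry the expected column set."""


class TaxdumpError(ProkmetaError):
    """Structural problem in a taxdump (dangling parent, cycle, bad line)."""


class UnknownTaxIdError(ProkmetaError):
    """A queried taxid is absent from the taxonomy database."""

    def __init__(self, taxid: int):
        self.taxid = taxid
        super().__init__(f"taxid {taxid} not found in taxonomy database")


class FilterSpecError(ProkmetaError):
    """Invalid filter specification (unknown rank, inverted range)."""


class FetchError(ProkmetaError):
    """Remote report could not be fetched and no usable cache exists."""
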