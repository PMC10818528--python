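"""Exception hierarchy shared across the package."""


class ToxraError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ToxraError):
    """An input table is missing a required column or has a malformed header."""


class RowError(ToxraError):
    """One or more data rows failed validation.

    Carries ``(row_index, message)`` tuples so callers can report every bad
    row at once instead of failing on the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems)
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}")


class RegistryError(ToxraError):
    """Registry-level violation (duplicate CAS, unknown CAS, empty registry)."""
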