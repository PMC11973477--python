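"""Exception hierarchy with stable CLI exit codes.

Each error class carries an ``exit_code`` so the command-line layer can map
failure modes to distinct process statuses: 2 bad input, 3 parse failure,
4 missing microstate energies, 5 packaged-data integrity.
"""

from __future__ import annotations


class MacropkaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(MacropkaError):
    """Invalid user input: bad values, violated preconditions, unknown keys."""

    exit_code = 2


class CapacityError(InputError):
    """Enumeration request exceeds the combinatorial guard."""


class ParseError(MacropkaError):
    """Malformed file content; carries the offending line number when known."""

    exit_code = 3

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ExtractionError(ParseError):
    """No free-energy marker found in a quantum-chemistry log."""


class MissingStateError(MacropkaError):
    """A required microstate has no free-energy record."""

    exit_code = 4

    def __init__(self, message: str, microstates: list[str] | None = None):
        super().__init__(message)
        self.microstates = microstates or []


class LadderGapError(MissingStateError):
    """A whole charge level is empty, so no stepwise pKa can bridge it."""


class DataIntegrityError(MacropkaError):
    """Packaged reference data failed its checksum."""

    exit_code = 5


class FitError(MacropkaError):
    """Degenerate regression design (e.g. zero variance in computed pKa)."""

    exit_code = 2
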