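"""Minimal free-energy extractor for quantum-chemistry text logs.

The external DFT stage prints the rigid-rotor-harmonic-oscillator Gibbs free
energy on a standard marker line; this module harvests that single value.
When a log contains several thermochemistry blocks (e.g. optimization
restarts) the last occurrence wins. Everything else in the log — geometries,
frequencies, thermal corrections — is out of scope.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import TextIO

from .errors import ExtractionError, ParseError

__all__ = ["extract_free_energy", "FREE_ENERGY_MARKER"]

#: whitespace-insensitive match for the standard Gibbs free-energy line
FREE_ENERGY_MARKER = re.compile(
    r"Sum\s+of\s+electronic\s+and\s+thermal\s+Free\s+Energies\s*=\s*(\S+)"
)


def extract_free_energy(source: str | Path | TextIO) -> tuple[float, int]:
    """Return (G in Hartree, number of marker occurrences) from a log.

    ``source`` may be a path, an open text stream, or the log text itself
    (anything containing a newline is treated as text).
    """
    if isinstance(source, io.TextIOBase):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<stream>")
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        lines = Path(source).read_text(errors="replace").splitlines()
        name = str(source)
    else:
        lines = str(source).splitlines()
        name = "<text>"

    value: float | None = None
    count = 0
    for lineno, line in enumerate(lines, start=1):
        m = FREE_ENERGY_MARKER.search(line)
        if not m:
            continue
        count += 1
        try:
            value = float(m.group(1))
        except ValueError:
            raise ParseError(
                f"{name}: unparsable free-energy value {m.group(1)!r}",
                line=lineno,
            ) from None
    if value is None:
        raise ExtractionError(f"{name}: no free-energy marker line found")
    return value, count
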