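"""Packaged tetra-aza macrocycle benchmark and prediction datasets.

``table1``: 32 experimental stepwise macroscopic pKa for ten synthesized
macrocycles paired with thermodynamic-cycle predictions
(M06-2X/def2-TZVP/SMD, proton-based cycle, lowest conformer per state) — the
data the linear empirical correction is fitted and validated on.

``table2``: corrected predictions for four not-yet-synthesized macrocycles
(11-14). Reference display only: recomputing them needs the external
conformer-sampling + DFT stages.

Files are verified against pinned SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataIntegrityError
from .lec import PkaObservation

__all__ = ["load_reference_dataset", "dataset_path"]

_DATASETS = {
    "table1": (
        "aza_macrocycle_pka_benchmark.tsv",
        "43fe717bc6a2e8e913ec27b0648686c35fc15c7b8695e4d79b9eede78829b59f",
    ),
    "table2": (
        "aza_macrocycle_pka_predictions.tsv",
        "dc00aebba3ae59b519403292ce926460d4ef4c42992430b6d513807464d512b4",
    ),
}


def dataset_path(name: str) -> Path:
    """Filesystem path of a packaged dataset (``table1`` or ``table2``)."""
    try:
        fname, _ = _DATASETS[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; available: {sorted(_DATASETS)}"
        ) from None
    return Path(str(resources.files("macropka").joinpath("data", fname)))


def _verified_frame(name: str) -> pd.DataFrame:
    fname, checksum = _DATASETS[name]
    path = dataset_path(name)
    blob = path.read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != checksum:
        raise DataIntegrityError(
            f"packaged dataset {fname} failed its SHA-256 check "
            f"(got {digest[:12]}..., expected {checksum[:12]}...)"
        )
    return pd.read_csv(path, sep="\t", comment="#", dtype={"molecule": str})


def load_reference_dataset(name: str):
    """Load a packaged dataset after checksum verification.

    ``table1`` returns a list of 32 :class:`~macropka.lec.PkaObservation`;
    ``table2`` returns a DataFrame of 8 predicted pKa over 4 molecules.
    """
    df = _verified_frame(name)
    if name == "table1":
        return [
            PkaObservation(
                molecule=row.molecule,
                step_index=int(row.step),
                experimental=float(row.experimental),
                computed=float(row.computed),
                source=row.source,
            )
            for row in df.itertuples()
        ]
    return df
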