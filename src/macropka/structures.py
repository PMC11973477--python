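"""Molecular structure I/O and per-microstate geometry generation.

The pipeline starts from a single 3D structure of the fully protonated
species plus an ordered list of exchangeable protons. Geometries for every
protonation microstate are produced by deleting protons from that template in
all combinations; the stripped geometries are written as-is (no relaxation —
conformational sampling and optimization belong to the external stages).

XYZ files carry ``charge=<int> microstate=<bitstring>`` on the comment line,
since plain XYZ has no native charge field. SDF uses V2000 with an explicit
charge block (via RDKit) so the net charge round-trips exactly. Atom indices
are 0-based in this API; user-facing config files use 1-based indices.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .errors import InputError, ParseError
from .microstates import MicrostateSet, enumerate_microstates

__all__ = [
    "MolecularStructure",
    "ProtonSite",
    "read_structure",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "write_sdf",
    "strip_protons",
    "prepare_microstate_geometries",
]

_PT = Chem.GetPeriodicTable()
SiteClass = Literal["aliphatic_amine", "pyridine", "oxygen", "other"]


def _valid_symbol(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass
class MolecularStructure:
    """An ordered list of atoms with Cartesian coordinates in Angstrom."""

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    net_charge: int = 0
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) < 1:
            raise InputError("structure must contain at least one atom")
        if self.coords.shape[0] != len(self.symbols):
            raise InputError("symbol and coordinate counts differ")
        if not np.isfinite(self.coords).all():
            raise InputError("coordinates must be finite")
        bad = [s for s in self.symbols if not _valid_symbol(s)]
        if bad:
            raise InputError(f"invalid element symbols: {sorted(set(bad))}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ProtonSite:
    """One exchangeable proton: the H atom and the heavy atom bearing it."""

    label: str
    heavy_atom_index: int
    proton_atom_index: int
    site_class: SiteClass = "other"

    def validate(self, structure: MolecularStructure) -> None:
        n = structure.n_atoms
        for idx in (self.heavy_atom_index, self.proton_atom_index):
            if not (0 <= idx < n):
                raise InputError(
                    f"site {self.label!r}: atom index {idx} out of bounds (n={n})"
                )
        if self.heavy_atom_index == self.proton_atom_index:
            raise InputError(f"site {self.label!r}: heavy atom equals proton atom")
        sym = structure.symbols[self.proton_atom_index]
        if sym != "H":
            raise InputError(
                f"site {self.label!r}: atom {self.proton_atom_index} is {sym}, "
                "not H"
            )


def _check_sites(sites: Sequence[ProtonSite], structure: MolecularStructure) -> None:
    labels = [s.label for s in sites]
    if len(set(labels)) != len(labels):
        raise InputError("site labels must be distinct")
    protons = [s.proton_atom_index for s in sites]
    if len(set(protons)) != len(protons):
        raise InputError("sites must reference distinct proton atoms")
    for s in sites:
        s.validate(structure)


_CHARGE_RE = re.compile(r"charge=(-?\d+)")


def read_xyz(path: str | Path) -> MolecularStructure:
    """Read a plain XYZ file; net charge is recovered from a ``charge=``
    token on the comment line when present, else 0."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as e:
        raise InputError(f"cannot read {path}: {e}") from None
    if not lines:
        raise ParseError(f"{path}: empty file", line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: first line must be the atom count", line=1)
    title = lines[1] if len(lines) > 1 else ""
    atom_lines = lines[2 : 2 + n]
    if len(atom_lines) < n:
        raise ParseError(
            f"{path}: header promises {n} atoms but only {len(atom_lines)} "
            "atom lines follow",
            line=len(lines) + 1,
        )
    symbols, coords = [], []
    for i, line in enumerate(atom_lines):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed atom line", line=i + 3)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: non-numeric coordinate", line=i + 3)
        symbols.append(parts[0])
        coords.append(xyz)
    m = _CHARGE_RE.search(title)
    charge = int(m.group(1)) if m else 0
    return MolecularStructure(symbols, np.array(coords), charge, title)


def write_xyz(structure: MolecularStructure, path: str | Path,
              comment: str | None = None) -> None:
    """Write plain XYZ; the comment line records charge (and any metadata
    passed in ``comment``) so it can be recovered on read."""
    if comment is None:
        comment = f"charge={structure.net_charge}"
        if structure.title and "charge=" not in structure.title:
            comment += f" {structure.title}"
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(structure.symbols, structure.coords):
            fh.write(f"{sym:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_sdf(path: str | Path) -> MolecularStructure:
    """Read the first record of an SDF/MOL V2000 file via RDKit.

    Net charge is the sum of the formal charges in the charge block.
    """
    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError(f"{path}: RDKit could not parse SDF/MOL record")
    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
    )
    charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return MolecularStructure(symbols, coords, charge, title)


def write_sdf(structure: MolecularStructure, path: str | Path) -> None:
    """Write a bond-less SDF V2000 record with an explicit charge block.

    The net charge is carried on the first atom so that the total formal
    charge round-trips exactly; per-atom charge placement is not tracked by
    :class:`MolecularStructure`.
    """
    mol = Chem.RWMol()
    for sym in structure.symbols:
        mol.AddAtom(Chem.Atom(sym))
    if structure.net_charge != 0:
        mol.GetAtomWithIdx(0).SetFormalCharge(int(structure.net_charge))
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(True)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(structure.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    m = mol.GetMol()
    m.SetProp("_Name", structure.title)
    with open(path, "w") as fh:
        fh.write(Chem.MolToMolBlock(m, kekulize=False))
        fh.write("$$$$\n")


def read_structure(
    path: str | Path,
    format: Literal["xyz", "sdf", "auto"] = "auto",
    net_charge: int | None = None,
) -> MolecularStructure:
    """Read XYZ or SDF; ``auto`` resolves the format from the extension.

    ``net_charge`` overrides the charge recovered from the file (XYZ files
    without a ``charge=`` token default to 0).
    """
    path = Path(path)
    if format == "auto":
        ext = path.suffix.lower().lstrip(".")
        if ext in ("xyz",):
            format = "xyz"
        elif ext in ("sdf", "mol"):
            format = "sdf"
        else:
            raise InputError(
                f"cannot resolve format from extension {path.suffix!r}; "
                "pass format='xyz' or 'sdf'"
            )
    if format == "xyz":
        st = read_xyz(path)
    elif format == "sdf":
        st = read_sdf(path)
    else:
        raise InputError(f"unknown format {format!r}")
    if net_charge is not None:
        st = replace(st, net_charge=int(net_charge))
    return st


def strip_protons(
    template: MolecularStructure,
    sites: Sequence[ProtonSite],
    remove: set[str] | Sequence[str],
) -> MolecularStructure:
    """Delete the protons of the named sites from the template.

    Remaining atom order is preserved and the net charge drops by one per
    removed proton.
    """
    remove_list = list(remove)
    if len(set(remove_list)) != len(remove_list):
        raise InputError(f"duplicate labels in removal set: {remove_list}")
    _check_sites(sites, template)
    by_label = {s.label: s for s in sites}
    try:
        drop = {by_label[lab].proton_atom_index for lab in remove_list}
    except KeyError as e:
        raise KeyError(f"unknown site label {e.args[0]!r}") from None
    keep = [i for i in range(template.n_atoms) if i not in drop]
    return MolecularStructure(
        [template.symbols[i] for i in keep],
        template.coords[keep],
        template.net_charge - len(drop),
        template.title,
    )


def prepare_microstate_geometries(
    template: MolecularStructure,
    sites: Sequence[ProtonSite],
    out_dir: str | Path,
    reference_charge: int | None = None,
) -> pd.DataFrame:
    """Write one XYZ geometry per protonation microstate.

    Files are named by occupancy bitstring (``1011.xyz``) in deterministic
    order (descending proton count, lexicographic within). Returns — and also
    writes as ``manifest.tsv`` — a manifest with columns microstate, charge,
    n_protons, path.
    """
    _check_sites(sites, template)
    if reference_charge is None:
        reference_charge = template.net_charge
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise InputError(f"output directory not writable: {e}") from None

    ms_set = enumerate_microstates([s.label for s in sites], reference_charge)
    rows = []
    for state in ms_set:
        removed = {
            lab for lab, bit in zip(ms_set.site_labels, state.occupancy) if not bit
        }
        geom = strip_protons(template, sites, removed)
        path = out_dir / f"{state.id or 'template'}.xyz"
        write_xyz(
            geom, path, comment=f"charge={geom.net_charge} microstate={state.id}"
        )
        rows.append(
            {
                "microstate": state.id,
                "charge": geom.net_charge,
                "n_protons": state.n_protons,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
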