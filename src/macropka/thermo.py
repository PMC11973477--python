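"""Thermodynamic-cycle conversion of microstate free energies to microscopic pKa.

The aqueous deprotonation HA^n (aq) -> H+ (aq) + A^(n-1) (aq) has

    pKa = [G(A, aq) + G(H+, aq) - G(HA, aq)] / (RT ln 10)

where the solute free energies come from an external conformer-sampling +
DFT/continuum-solvent stage and G(H+, aq) is the experimental aqueous proton
free energy assembled from three pieces: the ideal-gas proton free energy
(5/2)RT - T*S0 at 1 bar, the 1 atm -> 1 mol/L standard-state change
RT ln(24.46), and the proton aqueous solvation free energy (-265.9 kcal/mol,
Tissandier-derived). An alternative water-referenced cycle
HA + H2O -> H3O+ + A is provided for runs that use only computed solvation
free energies.

Internal energy unit is kcal/mol throughout; Hartree columns are converted on
ingest (627.5095 kcal/mol per Hartree).
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InputError, MissingStateError, ParseError
from .microstates import DeprotonationEdge, Microstate

__all__ = [
    "HARTREE_TO_KCAL",
    "ThermoConstants",
    "FreeEnergyRecord",
    "FreeEnergyTable",
    "MicroPka",
    "gas_phase_proton_G",
    "standard_state_correction",
    "proton_free_energy",
    "micro_pka",
    "micro_pka_water_cycle",
    "state_free_energy",
    "all_micro_pkas",
]

HARTREE_TO_KCAL = 627.5095

#: Molar volume of an ideal gas at 298.15 K and 1 atm, in litres; RT*ln(24.46)
#: is the free-energy cost of compressing 1 mol gas from 1 atm to 1 mol/L.
IDEAL_GAS_MOLAR_VOLUME_L = 24.46


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the proton thermodynamic cycle.

    Parameters
    ----------
    T : temperature in K.
    R : gas constant in kcal/(mol K).
    S0_gas_proton : standard gas-phase proton entropy in cal/(mol K)
        (Sackur-Tetrode at 1 bar).
    dG_1atm_to_1M : 1 atm -> 1 mol/L standard-state correction in kcal/mol;
        ``None`` means compute RT ln(24.46) from T and R.
    dG_solv_proton : aqueous proton solvation free energy, kcal/mol.
    hartree_to_kcal : unit conversion applied to Hartree inputs.
    """

    T: float = 298.15
    R: float = 1.98720e-3
    S0_gas_proton: float = 26.05
    dG_1atm_to_1M: float | None = None
    dG_solv_proton: float = -265.9
    hartree_to_kcal: float = HARTREE_TO_KCAL

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.R > 0):
            raise InputError("temperature and gas constant must be positive")
        vals = [self.T, self.R, self.S0_gas_proton, self.dG_solv_proton]
        if self.dG_1atm_to_1M is not None:
            vals.append(self.dG_1atm_to_1M)
        if not all(math.isfinite(v) for v in vals):
            raise InputError("thermodynamic constants must be finite")

    @property
    def RT(self) -> float:
        """Thermal energy, kcal/mol."""
        return self.R * self.T

    @property
    def RT_ln10(self) -> float:
        """kcal/mol per pKa unit; 1.3642 at the defaults."""
        return self.RT * math.log(10.0)


def gas_phase_proton_G(constants: ThermoConstants = ThermoConstants()) -> float:
    """Ideal-gas proton free energy (5/2)RT - T*S0 at 1 bar, kcal/mol.

    -6.286 kcal/mol at the defaults (commonly quoted rounded to -6.28).
    """
    return 2.5 * constants.RT - constants.T * constants.S0_gas_proton / 1000.0


def standard_state_correction(constants: ThermoConstants = ThermoConstants()) -> float:
    """RT ln(24.46): the 1 atm -> 1 mol/L change of standard state, kcal/mol."""
    if constants.dG_1atm_to_1M is not None:
        return constants.dG_1atm_to_1M
    return constants.RT * math.log(IDEAL_GAS_MOLAR_VOLUME_L)


def proton_free_energy(constants: ThermoConstants = ThermoConstants()) -> float:
    """Aqueous proton free energy G(H+, aq) at 1 mol/L, kcal/mol (~ -270.29)."""
    return (
        gas_phase_proton_G(constants)
        + standard_state_correction(constants)
        + constants.dG_solv_proton
    )


def micro_pka(
    G_donor: float,
    G_acceptor: float,
    constants: ThermoConstants = ThermoConstants(),
) -> float:
    """Microscopic pKa of one deprotonation via the proton-based cycle.

    ``G_donor`` and ``G_acceptor`` are aqueous free energies (kcal/mol) of the
    protonated and deprotonated microstate.
    """
    if not (math.isfinite(G_donor) and math.isfinite(G_acceptor)):
        raise InputError("free energies must be finite")
    dG = G_acceptor + proton_free_energy(constants) - G_donor
    return dG / constants.RT_ln10


def micro_pka_water_cycle(
    G_donor: float,
    G_acceptor: float,
    G_water: float,
    G_hydronium: float,
    constants: ThermoConstants = ThermoConstants(),
    offset: float = 0.0,
) -> float:
    """Microscopic pKa via the water-referenced cycle HA + H2O -> H3O+ + A.

    ``offset`` (kcal/mol) is a hook for constant post-hoc corrections such as
    a water standard-state term; default 0.
    """
    vals = (G_donor, G_acceptor, G_water, G_hydronium, offset)
    if not all(math.isfinite(v) for v in vals):
        raise InputError("free energies must be finite")
    dG = G_acceptor + G_hydronium - G_donor - G_water + offset
    return dG / constants.RT_ln10


@dataclass(frozen=True)
class FreeEnergyRecord:
    """One conformer's Gibbs free energy for one protonation microstate."""

    molecule: str
    microstate: str
    conformer_rank: int
    G: float  # kcal/mol
    method: str = ""


@dataclass(frozen=True)
class MicroPka:
    """A microscopic pKa on one deprotonation edge of the hypercube."""

    donor: str
    acceptor: str
    site: str
    pka: float


_TSV_COLUMNS = ["molecule", "microstate", "charge", "conformer", "G", "unit", "method"]

ConformerMode = Literal["min", "boltzmann"]


@dataclass
class FreeEnergyTable:
    """Per-microstate, per-conformer Gibbs free energies (kcal/mol).

    The pipeline's central exchange format: the product of the external
    CREST + DFT stages (or of the surrogate generator), keyed by molecule id
    and microstate bitstring.
    """

    records: pd.DataFrame
    site_count: int
    reference_charge: int

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"molecule", "microstate", "conformer", "G"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"free-energy table missing columns: {sorted(missing)}")
        if "method" not in df.columns:
            df["method"] = ""
        df = df.astype(
            {"molecule": str, "microstate": str, "conformer": int, "G": float}
        )
        bad = df[df["microstate"].str.len() != self.site_count]
        if len(bad):
            raise InputError(
                f"microstate ids must have length {self.site_count}; "
                f"offending ids: {sorted(set(bad['microstate']))[:5]}"
            )
        if not df["microstate"].str.fullmatch("[01]*").all():
            raise InputError("microstate ids must be 0/1 bitstrings")
        if df.duplicated(["molecule", "microstate", "conformer", "method"]).any():
            raise InputError(
                "duplicate (molecule, microstate, conformer, method) records"
            )
        if not np.isfinite(df["G"]).all():
            raise InputError("free energies must be finite")
        self.records = df.reset_index(drop=True)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[FreeEnergyRecord],
        site_count: int,
        reference_charge: int,
    ) -> "FreeEnergyTable":
        rows = [
            {
                "molecule": r.molecule,
                "microstate": r.microstate,
                "conformer": r.conformer_rank,
                "G": r.G,
                "method": r.method,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows), site_count, reference_charge)

    @classmethod
    def from_state_energies(
        cls,
        energies: dict[str, float],
        reference_charge: int,
        molecule: str = "mol",
        method: str = "",
    ) -> "FreeEnergyTable":
        """Build a single-conformer table from {bitstring: G_kcal}."""
        if not energies:
            raise InputError("empty energy mapping")
        n = len(next(iter(energies)))
        rows = [
            {"molecule": molecule, "microstate": s, "conformer": 1, "G": g,
             "method": method}
            for s, g in energies.items()
        ]
        return cls(pd.DataFrame(rows), n, reference_charge)

    @classmethod
    def read_tsv(
        cls, path: str | Path | io.TextIOBase, site_count: int | None = None,
        reference_charge: int | None = None,
    ) -> "FreeEnergyTable":
        """Read the standard tab-separated free-energy format.

        Header required; '#' starts a comment; column ``unit`` is ``hartree``
        or ``kcal_mol`` and is applied per row on ingest.
        """
        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
            raise ParseError(f"cannot read free-energy TSV: {e}") from None
        missing = set(_TSV_COLUMNS[:6]) - set(df.columns) - {"charge"}
        if missing:
            raise ParseError(
                f"free-energy TSV missing required columns: {sorted(missing)}"
            )
        try:
            g = df["G"].astype(float)
            conformer = df["conformer"].astype(int)
        except ValueError as e:
            raise ParseError(f"non-numeric G or conformer column: {e}") from None
        unit = df["unit"].str.strip().str.lower()
        unknown = set(unit) - {"hartree", "kcal_mol"}
        if unknown:
            raise ParseError(f"unknown energy units: {sorted(unknown)}")
        g = np.where(unit == "hartree", g * HARTREE_TO_KCAL, g)
        out = pd.DataFrame(
            {
                "molecule": df["molecule"].str.strip(),
                "microstate": df["microstate"].str.strip(),
                "conformer": conformer,
                "G": g,
                "method": df.get("method", pd.Series([""] * len(df))).fillna(""),
            }
        )
        n = site_count if site_count is not None else int(
            out["microstate"].str.len().max()
        )
        ref = reference_charge
        if ref is None and "charge" in df.columns:
            # reference charge = charge of the fully protonated state if present
            full = out["microstate"] == "1" * n
            if full.any():
                ref = int(df.loc[full, "charge"].astype(int).iloc[0])
        if ref is None:
            ref = 0
        return cls(out, n, ref)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, unit: str = "kcal_mol") -> None:
        df = self.records.copy()
        df["charge"] = [self.charge_of(s) for s in df["microstate"]]
        if unit == "hartree":
            df["G"] = df["G"] / HARTREE_TO_KCAL
        elif unit != "kcal_mol":
            raise InputError(f"unknown unit {unit!r}")
        df["unit"] = unit
        df = df[_TSV_COLUMNS]
        with open(path, "w") as fh:
            fh.write("# macropka free-energy table\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10f")

    # -- queries -----------------------------------------------------------

    def charge_of(self, microstate: str) -> int:
        return self.reference_charge - (self.site_count - microstate.count("1"))

    @property
    def molecules(self) -> list[str]:
        return sorted(set(self.records["molecule"]))

    def _resolve_molecule(self, molecule: str | None) -> str:
        if molecule is not None:
            return molecule
        mols = self.molecules
        if len(mols) != 1:
            raise InputError(
                f"table holds {len(mols)} molecules; specify which one"
            )
        return mols[0]

    def microstates_present(self, molecule: str | None = None) -> set[str]:
        molecule = self._resolve_molecule(molecule)
        sub = self.records[self.records["molecule"] == molecule]
        return set(sub["microstate"])

    def missing_microstates(self, molecule: str | None = None) -> list[str]:
        present = self.microstates_present(molecule)
        universe = {
            "".join(bits)
            for bits in itertools.product("01", repeat=self.site_count)
        }
        return sorted(universe - present)

    def conformer_energies(
        self, molecule: str | None, microstate: str
    ) -> np.ndarray:
        molecule = self._resolve_molecule(molecule)
        mask = (self.records["molecule"] == molecule) & (
            self.records["microstate"] == microstate
        )
        return self.records.loc[mask, "G"].to_numpy()


def state_free_energy(
    table: FreeEnergyTable,
    molecule: str | None,
    microstate: str,
    constants: ThermoConstants = ThermoConstants(),
    mode: ConformerMode = "min",
) -> float:
    """Free energy of one protonation state from its conformer ensemble.

    ``min`` (default) takes the lowest-energy conformer; ``boltzmann`` takes
    the ensemble free energy -RT ln sum(exp(-G_i/RT)), evaluated in log space.
    """
    g = table.conformer_energies(molecule, microstate)
    if g.size == 0:
        raise MissingStateError(
            f"no free-energy record for microstate {microstate!r}",
            microstates=[microstate],
        )
    if mode == "min":
        return float(g.min())
    if mode == "boltzmann":
        return float(-constants.RT * logsumexp(-g / constants.RT))
    raise InputError(f"unknown conformer mode {mode!r}")


def all_micro_pkas(
    table: FreeEnergyTable,
    edges: Sequence[DeprotonationEdge],
    constants: ThermoConstants = ThermoConstants(),
    molecule: str | None = None,
    mode: ConformerMode = "min",
    strict: bool = False,
) -> list[MicroPka]:
    """Microscopic pKa for every deprotonation edge covered by the table.

    Edges touching a microstate with no energy record are skipped with a
    warning (default) or raise :class:`MissingStateError` when ``strict``.
    Output order matches edge order.
    """
    molecule = table._resolve_molecule(molecule)
    present = table.microstates_present(molecule)
    missing_hit: set[str] = set()
    cache: dict[str, float] = {}

    def energy(state: Microstate) -> float:
        sid = state.id
        if sid not in cache:
            cache[sid] = state_free_energy(table, molecule, sid, constants, mode)
        return cache[sid]

    out: list[MicroPka] = []
    for edge in edges:
        ids = {edge.donor.id, edge.acceptor.id}
        absent = ids - present
        if absent:
            missing_hit |= absent
            continue
        out.append(
            MicroPka(
                donor=edge.donor.id,
                acceptor=edge.acceptor.id,
                site=edge.site,
                pka=micro_pka(energy(edge.donor), energy(edge.acceptor), constants),
            )
        )
    if missing_hit:
        msg = f"microstates without energies: {sorted(missing_hit)}"
        if strict:
            raise MissingStateError(msg, microstates=sorted(missing_hit))
        warnings.warn(msg, stacklevel=2)
    return out


def micro_pkas_frame(pkas: Sequence[MicroPka]) -> pd.DataFrame:
    """Tabulate a list of microscopic pKas."""
    return pd.DataFrame(
        [{"donor": p.donor, "acceptor": p.acceptor, "site": p.site, "pka": p.pka}
         for p in pkas]
    )
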