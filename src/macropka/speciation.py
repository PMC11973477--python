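"""Macroscopic pKa ladders, dominant protomers, and pH-dependent speciation.

Experiment measures *macroscopic* stepwise pKa between adjacent total-charge
states; each charge state aggregates all its protomers. Two aggregation modes
are supported:

``min_state``
    Each charge level is represented by its lowest-free-energy protomer
    (lowest-energy conformation of each protonation state) — the default.
``boltzmann``
    Each charge level is represented by the ensemble free energy
    -RT ln sum(exp(-G/RT)) over its protomers, i.e. the binding-polynomial
    result including statistical factors.

The two ladders differ by at most log10(m) where m is the largest number of
protomers in a charge level. Speciation weights each microstate s by
exp(-[G(s) - n_s*mu_H(pH)]/RT) with proton chemical potential
mu_H = G(H+, aq) - RT ln10 * pH; all population arithmetic is done in log
space because |G| of a multiply protonated macrocycle is hundreds of
kcal/mol.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InputError, LadderGapError
from .thermo import (
    FreeEnergyTable,
    ThermoConstants,
    proton_free_energy,
    state_free_energy,
)

__all__ = [
    "LadderMode",
    "MacroStep",
    "MacroLadder",
    "ProtomerAssignment",
    "SpeciationProfile",
    "macro_pka_ladder",
    "dominant_protomers",
    "speciation_curves",
    "titration_midpoints",
    "default_ph_grid",
]

LadderMode = Literal["min_state", "boltzmann"]


def default_ph_grid(start: float = 0.0, stop: float = 14.0,
                    step: float = 0.05) -> np.ndarray:
    return np.round(np.arange(start, stop + step / 2, step), 10)


@dataclass(frozen=True)
class MacroStep:
    """One stepwise deprotonation between adjacent charge states.

    Step indices follow the experimental numbering: step 1 is the most basic
    transition (the lowest adjacent charge pair, last to deprotonate on a
    titration from low pH), step N the most acidic.
    """

    index: int
    donor_charge: int
    acceptor_charge: int
    donor_microstate: str  # min-G representative of the donor charge level
    acceptor_microstate: str
    pka: float


@dataclass
class MacroLadder:
    """Ordered stepwise macroscopic pKa, step 1 (most basic) first."""

    steps: list[MacroStep]
    mode: LadderMode

    @property
    def pkas(self) -> list[float]:
        return [s.pka for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.index,
                    "donor_charge": s.donor_charge,
                    "acceptor_charge": s.acceptor_charge,
                    "donor_microstate": s.donor_microstate,
                    "acceptor_microstate": s.acceptor_microstate,
                    "pka": s.pka,
                }
                for s in self.steps
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"mode": self.mode, "steps": self.to_frame().to_dict("records")}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _charge_levels(
    table: FreeEnergyTable, molecule: str | None
) -> dict[int, list[str]]:
    """Microstate ids with energy records, grouped by net charge."""
    present = sorted(table.microstates_present(molecule))
    levels: dict[int, list[str]] = {}
    for sid in present:
        levels.setdefault(table.charge_of(sid), []).append(sid)
    return levels


def _level_free_energy(
    table: FreeEnergyTable,
    molecule: str | None,
    ids: list[str],
    constants: ThermoConstants,
    mode: LadderMode,
) -> tuple[float, str]:
    """(representative free energy, min-G microstate id) for a charge level."""
    energies = np.array(
        [state_free_energy(table, molecule, sid, constants) for sid in ids]
    )
    best = int(np.argmin(energies))
    # ties resolved by lexicographic id because ids are pre-sorted
    if mode == "min_state":
        return float(energies[best]), ids[best]
    if mode == "boltzmann":
        g = float(-constants.RT * logsumexp(-energies / constants.RT))
        return g, ids[best]
    raise InputError(f"unknown ladder mode {mode!r}")


def macro_pka_ladder(
    table: FreeEnergyTable,
    constants: ThermoConstants = ThermoConstants(),
    mode: LadderMode = "min_state",
    molecule: str | None = None,
) -> MacroLadder:
    """Stepwise macroscopic pKa, numbered most-basic-first.

    Step k bridges charge (c_min + k) -> (c_min + k - 1); its pKa is
    [G(level c-1) + G(H+) - G(level c)] / (RT ln 10) with the per-level free
    energy set by ``mode``, so step 1 is the most basic transition, matching
    the experimental numbering. Raises :class:`LadderGapError` when a charge
    level between the extremes has no energy records.
    """
    levels = _charge_levels(table, molecule)
    if not levels:
        raise LadderGapError("free-energy table is empty")
    charges = sorted(levels)  # ascending: lowest (most basic pair) first
    missing = [c for c in range(charges[0], charges[-1] + 1) if c not in levels]
    if missing:
        raise LadderGapError(
            f"no microstate energies at charge level(s) {missing}; "
            "cannot bridge the ladder"
        )
    g_h = proton_free_energy(constants)
    reps = {
        c: _level_free_energy(table, molecule, levels[c], constants, mode)
        for c in charges
    }
    steps = []
    for k, c in enumerate(charges[1:], start=1):
        g_donor, id_donor = reps[c]
        g_acceptor, id_acceptor = reps[c - 1]
        pka = (g_acceptor + g_h - g_donor) / constants.RT_ln10
        steps.append(MacroStep(k, c, c - 1, id_donor, id_acceptor, pka))
    return MacroLadder(steps, mode)


@dataclass
class ProtomerAssignment:
    """Per charge state: the minimum-free-energy protomer and its margin."""

    # charge -> (microstate id, G kcal/mol, gap to runner-up kcal/mol)
    by_charge: dict[int, tuple[str, float, float]]

    def protomer(self, charge: int) -> str:
        return self.by_charge[charge][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"charge": c, "microstate": sid, "G": g, "gap_to_runner_up": gap}
                for c, (sid, g, gap) in sorted(
                    self.by_charge.items(), reverse=True
                )
            ]
        )


def dominant_protomers(
    table: FreeEnergyTable,
    constants: ThermoConstants = ThermoConstants(),
    molecule: str | None = None,
) -> ProtomerAssignment:
    """Most stable protomer of each charge state.

    Exact ties break to the lexicographically smallest bitstring and emit a
    warning carrying the (zero) gap; a charge level with a single protomer
    reports an infinite gap.
    """
    levels = _charge_levels(table, molecule)
    out: dict[int, tuple[str, float, float]] = {}
    for charge, ids in levels.items():
        energies = [
            state_free_energy(table, molecule, sid, constants) for sid in ids
        ]
        order = sorted(range(len(ids)), key=lambda i: (energies[i], ids[i]))
        best = order[0]
        gap = (
            energies[order[1]] - energies[best] if len(ids) > 1 else math.inf
        )
        if len(ids) > 1 and gap == 0.0:
            warnings.warn(
                f"charge {charge:+d}: degenerate protomers "
                f"{ids[best]!r} and {ids[order[1]]!r} (gap {gap} kcal/mol); "
                "choosing the lexicographically smaller id",
                stacklevel=2,
            )
        out[charge] = (ids[best], energies[best], gap)
    return ProtomerAssignment(out)


@dataclass
class SpeciationProfile:
    """Microstate and charge-state populations on a pH grid."""

    pH: np.ndarray
    fractions: pd.DataFrame  # one column per microstate id, rows = pH grid
    charge_fractions: pd.DataFrame  # one column per charge (int)

    def to_csv(self, path: str | Path) -> None:
        df = self.fractions.copy()
        for c in self.charge_fractions.columns:
            df[f"charge_{c:+d}"] = self.charge_fractions[c]
        df.insert(0, "pH", self.pH)
        df.to_csv(path, index=False)

    def plot(self, ax=None, by_charge: bool = True):
        """Basic speciation diagram (population fraction vs pH)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.charge_fractions if by_charge else self.fractions
        for col in frame.columns:
            label = f"charge {col:+d}" if by_charge else str(col)
            ax.plot(self.pH, frame[col], label=label)
        ax.set_xlabel("pH")
        ax.set_ylabel("population fraction")
        ax.set_ylim(0, 1)
        ax.legend(fontsize="small")
        return ax


def speciation_curves(
    table: FreeEnergyTable,
    constants: ThermoConstants = ThermoConstants(),
    pH_grid: Sequence[float] | None = None,
    molecule: str | None = None,
    allow_partial: bool = False,
) -> SpeciationProfile:
    """Grand-canonical microstate populations as a function of pH.

    State s gets log-weight -[G(s) - n_s*mu_H(pH)]/RT with
    mu_H = G(H+, aq) - RT ln10 * pH, normalized over all states at each pH
    (log-sum-exp). Pass ``allow_partial=True`` to accept a table that does not
    cover the full 2^N enumeration.
    """
    molecule = table._resolve_molecule(molecule)
    pH = default_ph_grid() if pH_grid is None else np.asarray(pH_grid, float)
    if pH.ndim != 1 or len(pH) < 2 or not np.all(np.diff(pH) > 0):
        raise InputError("pH grid must be strictly increasing with >= 2 points")
    missing = table.missing_microstates(molecule)
    if missing and not allow_partial:
        raise InputError(
            f"table covers {2 ** table.site_count - len(missing)} of "
            f"{2 ** table.site_count} microstates (missing e.g. "
            f"{missing[:4]}); pass allow_partial=True to proceed"
        )
    ids = sorted(table.microstates_present(molecule))
    g = np.array(
        [state_free_energy(table, molecule, sid, constants) for sid in ids]
    )
    n_protons = np.array([sid.count("1") for sid in ids])
    mu = proton_free_energy(constants) - constants.RT_ln10 * pH  # (n_pH,)
    # log-weights, states x pH
    lw = -(g[:, None] - n_protons[:, None] * mu[None, :]) / constants.RT
    lw -= logsumexp(lw, axis=0, keepdims=True)
    fractions = pd.DataFrame(np.exp(lw).T, columns=ids)
    charges = sorted({table.charge_of(sid) for sid in ids}, reverse=True)
    charge_fractions = pd.DataFrame(
        {
            c: fractions[
                [sid for sid in ids if table.charge_of(sid) == c]
            ].sum(axis=1)
            for c in charges
        }
    )
    return SpeciationProfile(pH, fractions, charge_fractions)


def titration_midpoints(
    profile: SpeciationProfile,
) -> list[tuple[tuple[int, int], float]]:
    """pH where adjacent charge-state populations cross.

    Linear interpolation between grid points; adjacent pairs whose curves do
    not cross inside the grid are omitted with a warning. At the crossing of
    per-charge Boltzmann weights the pH equals the boltzmann-mode ladder
    step. Ordered like the ladder: lowest charge pair (most basic) first.
    """
    charges = sorted(profile.charge_fractions.columns)
    out: list[tuple[tuple[int, int], float]] = []
    for lo, hi in zip(charges[:-1], charges[1:]):
        diff = (
            profile.charge_fractions[hi] - profile.charge_fractions[lo]
        ).to_numpy()
        sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if sign_change.size == 0:
            warnings.warn(
                f"no crossing of charge {hi:+d}/{lo:+d} populations inside "
                "the pH grid",
                stacklevel=2,
            )
            continue
        i = int(sign_change[0])
        x0, x1 = profile.pH[i], profile.pH[i + 1]
        y0, y1 = diff[i], diff[i + 1]
        ph = x0 if y0 == y1 else x0 - y0 * (x1 - x0) / (y1 - y0)
        out.append(((hi, lo), float(ph)))
    return out
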