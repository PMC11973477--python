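"""End-to-end orchestration: free-energy table in, pKa bundle out.

`run_pipeline` ties the stages together for one molecule: enumerate
microstates, compute microscopic pKa over the deprotonation hypercube, build
the macroscopic ladder, assign dominant protomers, compute speciation
curves, and optionally apply the linear empirical correction. The external
conformer-sampling/DFT stages sit upstream and communicate through the
free-energy table.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .lec import LECModel, apply_lec, fit_lec
from .microstates import (
    MicrostateSet,
    deprotonation_edges,
    enumerate_microstates,
)
from .speciation import (
    LadderMode,
    MacroLadder,
    ProtomerAssignment,
    SpeciationProfile,
    default_ph_grid,
    dominant_protomers,
    macro_pka_ladder,
    speciation_curves,
)
from .structures import ProtonSite
from .thermo import FreeEnergyTable, MicroPka, ThermoConstants, micro_pkas_frame

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Site atom indices are 1-based here (file convention) and converted to the
    0-based programmatic indices on use.
    """

    sites: list[dict[str, Any]] = field(default_factory=list)
    structure_path: str | None = None
    reference_charge: int = 0
    constants: ThermoConstants = field(default_factory=ThermoConstants)
    ladder_mode: LadderMode = "min_state"
    lec_source: str = "none"  # none | fit_from_reference | explicit
    lec_a: float | None = None
    lec_b: float | None = None
    out_dir: str = "macropka_out"
    seed: int = 0
    verbosity: int = 1
    molecule: str | None = None

    def __post_init__(self) -> None:
        if self.lec_source not in ("none", "fit_from_reference", "explicit"):
            raise InputError(f"unknown lec_source {self.lec_source!r}")
        if self.lec_source == "explicit" and (
            self.lec_a is None or self.lec_b is None
        ):
            raise InputError("explicit LEC requires both lec_a and lec_b")
        for s in self.sites:
            if "label" not in s:
                raise InputError("every site entry needs a 'label'")

    @property
    def site_labels(self) -> list[str]:
        return [str(s["label"]) for s in self.sites]

    def proton_sites(self) -> list[ProtonSite]:
        """Sites as 0-based :class:`ProtonSite` (requires atom indices)."""
        out = []
        for s in self.sites:
            try:
                out.append(
                    ProtonSite(
                        label=str(s["label"]),
                        heavy_atom_index=int(s["heavy_atom"]) - 1,
                        proton_atom_index=int(s["proton_atom"]) - 1,
                        site_class=s.get("site_class", "other"),
                    )
                )
            except KeyError as e:
                raise InputError(
                    f"site {s.get('label')!r} missing field {e.args[0]!r}"
                ) from None
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        const = raw.pop("constants", {})
        if const:
            raw["constants"] = ThermoConstants(**const)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything one run computes, with writers for the standard formats."""

    config: RunConfig
    microstate_set: MicrostateSet
    micro_pkas: list[MicroPka]
    ladder: MacroLadder
    protomers: ProtomerAssignment
    speciation: SpeciationProfile | None
    lec_model: LECModel | None
    corrected_ladder_pkas: list[float] | None
    warnings_emitted: list[str]

    def summary(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "n_sites": self.microstate_set.n_sites,
            "n_microstates": len(self.microstate_set),
            "reference_charge": self.microstate_set.reference_charge,
            "ladder_mode": self.ladder.mode,
            "macro_pkas": self.ladder.pkas,
            "dominant_protomers": {
                str(c): sid
                for c, (sid, _, _) in sorted(
                    self.protomers.by_charge.items(), reverse=True
                )
            },
            "warnings": self.warnings_emitted,
        }
        if self.lec_model is not None:
            d["lec"] = {"a": self.lec_model.a, "b": self.lec_model.b}
            d["macro_pkas_corrected"] = self.corrected_ladder_pkas
        return d

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)

    def write(self, out_dir: str | Path | None = None) -> Path:
        out = Path(out_dir if out_dir is not None else self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.microstate_set.to_tsv(out / "roster.tsv")
        micro_pkas_frame(self.micro_pkas).to_csv(
            out / "micro_pkas.tsv", sep="\t", index=False
        )
        self.ladder.to_tsv(out / "ladder.tsv")
        self.ladder.to_json(out / "ladder.json")
        self.protomers.to_frame().to_csv(
            out / "protomers.tsv", sep="\t", index=False
        )
        if self.speciation is not None:
            self.speciation.to_csv(out / "speciation.csv")
        (out / "summary.json").write_text(self.summary_json() + "\n")
        return out


def run_pipeline(config: RunConfig, energies: FreeEnergyTable) -> PipelineResult:
    """Run enumeration → microscopic pKa → ladder → speciation (+ LEC).

    Missing microstate energies are tolerated: affected hypercube edges are
    skipped and speciation runs over the covered states, with the skipped ids
    reported in the bundle's warning list. Identical config + table give an
    identical bundle.
    """
    labels = config.site_labels or [
        f"S{i + 1}" for i in range(energies.site_count)
    ]
    if len(labels) != energies.site_count:
        raise InputError(
            f"config lists {len(labels)} sites but the table has "
            f"{energies.site_count}"
        )
    ms_set = enumerate_microstates(labels, energies.reference_charge)
    edges = deprotonation_edges(ms_set)

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        from .thermo import all_micro_pkas

        pkas = all_micro_pkas(
            energies, edges, config.constants, molecule=config.molecule
        )
        ladder = macro_pka_ladder(
            energies, config.constants, mode=config.ladder_mode,
            molecule=config.molecule,
        )
        protomers = dominant_protomers(
            energies, config.constants, molecule=config.molecule
        )
        speciation = speciation_curves(
            energies,
            config.constants,
            pH_grid=default_ph_grid(),
            molecule=config.molecule,
            allow_partial=True,
        )
        captured = sorted({str(w.message) for w in wlist})

    lec_model: LECModel | None = None
    corrected: list[float] | None = None
    if config.lec_source == "fit_from_reference":
        from .reference import load_reference_dataset

        lec_model = fit_lec(load_reference_dataset("table1"))
    elif config.lec_source == "explicit":
        lec_model = LECModel(
            a=float(config.lec_a), b=float(config.lec_b), n_obs=0,
            rmsd_uncorrected=float("nan"), rmsd_corrected=float("nan"),
        )
    if lec_model is not None:
        corrected = [float(apply_lec(lec_model, p)) for p in ladder.pkas]

    return PipelineResult(
        config=config,
        microstate_set=ms_set,
        micro_pkas=pkas,
        ladder=ladder,
        protomers=protomers,
        speciation=speciation,
        lec_model=lec_model,
        corrected_ladder_pkas=corrected,
        warnings_emitted=captured,
    )
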