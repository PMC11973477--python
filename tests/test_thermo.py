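"""Thermodynamic constants, cycles, and microscopic pKa."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macropka import (
    FreeEnergyTable,
    HARTREE_TO_KCAL,
    InputError,
    MissingStateError,
    ThermoConstants,
    all_micro_pkas,
    deprotonation_edges,
    enumerate_microstates,
    gas_phase_proton_G,
    micro_pka,
    micro_pka_water_cycle,
    proton_free_energy,
    standard_state_correction,
    state_free_energy,
)
from macropka.surrogate import closed_form_micro_pka, surrogate_free_energies

from conftest import random_state_energies

C = ThermoConstants()


class TestProtonFreeEnergy:
    def test_gas_phase_proton_matches_sackur_tetrode_value(self):
        """(5/2)RT - T*S0 at 298.15 K with S0 = 26.05 cal/(mol K) ~ -6.28."""
        assert gas_phase_proton_G(C) == pytest.approx(-6.286, abs=5e-4)
        assert round(gas_phase_proton_G(C), 2) == -6.29  # -6.28 is the
        # commonly printed truncation; the unrounded value is -6.2856

    def test_standard_state_correction_is_rt_ln_24_46(self):
        assert standard_state_correction(C) == pytest.approx(1.894, abs=5e-4)
        assert round(standard_state_correction(C), 2) == pytest.approx(1.89)

    def test_doubling_entropy_lowers_g_by_ts(self):
        c2 = ThermoConstants(S0_gas_proton=2 * 26.05)
        drop = gas_phase_proton_G(C) - gas_phase_proton_G(c2)
        assert drop == pytest.approx(298.15 * 26.05 / 1000, abs=1e-9)
        assert drop == pytest.approx(7.767, abs=1e-3)

    def test_correction_increases_with_temperature(self):
        temps = [250.0, 298.15, 350.0]
        vals = [
            standard_state_correction(ThermoConstants(T=t)) for t in temps
        ]
        assert vals == sorted(vals)

    def test_total_proton_free_energy(self):
        """Sum of the three printed components: -6.28 + 1.89 - 265.9."""
        assert proton_free_energy(C) == pytest.approx(-270.29, abs=0.01)

    def test_solvation_term_enters_linearly(self):
        c0 = ThermoConstants(dG_solv_proton=0.0)
        assert proton_free_energy(c0) == pytest.approx(-4.39, abs=0.01)
        for shift in (-10.0, 5.0):
            cs = ThermoConstants(dG_solv_proton=shift)
            assert proton_free_energy(cs) - proton_free_energy(c0) == (
                pytest.approx(shift, abs=1e-12)
            )

    def test_rt_ln10_reproducible(self):
        assert C.RT_ln10 == pytest.approx(1.3642, abs=5e-5)

    def test_invalid_constants_rejected(self):
        with pytest.raises(InputError):
            ThermoConstants(T=-1.0)
        with pytest.raises(InputError):
            ThermoConstants(dG_solv_proton=float("nan"))


class TestMicroPka:
    def test_zero_when_energy_gap_cancels_proton(self):
        g_h = proton_free_energy(C)
        assert micro_pka(0.0, -g_h, C) == pytest.approx(0.0, abs=1e-9)

    def test_benchmark_scale_value(self):
        # inverse arithmetic: dG* = 284.93 - 270.29 = 14.64; /1.3642 = 10.73
        assert micro_pka(0.0, 284.93, C) == pytest.approx(10.73, abs=0.01)

    @given(st.floats(-500, 500), st.floats(-500, 500), st.floats(-200, 200))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_antisymmetry(self, gd, ga, c):
        assert micro_pka(gd + c, ga + c, C) == pytest.approx(
            micro_pka(gd, ga, C), abs=1e-6
        )
        # the state-function part is antisymmetric under donor/acceptor
        # exchange; the constant proton-reference term drops out of the sum
        assert micro_pka(gd, ga, C) + micro_pka(ga, gd, C) == pytest.approx(
            2 * micro_pka(0.0, 0.0, C), abs=1e-6
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            micro_pka(float("inf"), 0.0, C)


class TestWaterCycle:
    def test_coincides_with_proton_cycle_when_hydronium_reference_matches(self):
        g_w, g_h3o = -100.0, -100.0 + proton_free_energy(C)
        assert micro_pka_water_cycle(5.0, 270.0, g_w, g_h3o, C) == (
            pytest.approx(micro_pka(5.0, 270.0, C), abs=1e-9)
        )

    def test_shift_invariance_over_all_four_species(self):
        base = micro_pka_water_cycle(1.0, 2.0, 3.0, 4.0, C)
        shifted = micro_pka_water_cycle(1.0 + 7, 2.0 + 7, 3.0 + 7, 4.0 + 7, C)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_reverse_reaction_flips_sign(self):
        """Exchanging donor with acceptor *and* water with hydronium
        describes the reverse reaction, whose pKa is sign-flipped."""
        a = micro_pka_water_cycle(1.0, 2.0, 3.0, 4.0, C)
        b = micro_pka_water_cycle(2.0, 1.0, 4.0, 3.0, C)
        assert a == pytest.approx(-b, abs=1e-9)
        # with a symmetric reference (water == hydronium energy) the plain
        # donor/acceptor swap is already antisymmetric
        c_ = micro_pka_water_cycle(1.0, 2.0, 3.0, 3.0, C)
        d_ = micro_pka_water_cycle(2.0, 1.0, 3.0, 3.0, C)
        assert c_ == pytest.approx(-d_, abs=1e-9)

    def test_offset_hook_moves_pka_linearly(self):
        a = micro_pka_water_cycle(1.0, 2.0, 3.0, 4.0, C, offset=0.0)
        b = micro_pka_water_cycle(1.0, 2.0, 3.0, 4.0, C, offset=C.RT_ln10)
        assert b - a == pytest.approx(1.0, abs=1e-9)


class TestFreeEnergyTable:
    def test_conformer_min_and_boltzmann(self):
        table = FreeEnergyTable.from_state_energies({"1": 0.0, "0": 0.0}, 1)
        rows = table.records
        import pandas as pd

        extra = pd.DataFrame(
            [
                {"molecule": "mol", "microstate": "1", "conformer": 2,
                 "G": 12.0, "method": ""},
                {"molecule": "mol", "microstate": "1", "conformer": 3,
                 "G": 11.0, "method": ""},
            ]
        )
        t2 = FreeEnergyTable(pd.concat([rows, extra]), 1, 1)
        t2.records.loc[t2.records["conformer"] == 1, "G"] = 10.0
        assert state_free_energy(t2, None, "1", C, mode="min") == 10.0
        boltz = state_free_energy(t2, None, "1", C, mode="boltzmann")
        assert boltz <= 10.0  # log-sum-exp lower bound

    def test_missing_state_error_names_the_microstate(self):
        table = FreeEnergyTable.from_state_energies({"1": 0.0}, 1)
        with pytest.raises(MissingStateError) as e:
            state_free_energy(table, None, "0", C)
        assert e.value.microstates == ["0"]

    def test_hartree_and_kcal_ingest_agree(self, tmp_path):
        energies = {"11": -700.123456, "10": -700.1, "01": -700.2,
                    "00": -700.05}
        header = "molecule\tmicrostate\tcharge\tconformer\tG\tunit\tmethod\n"
        kcal_rows = "".join(
            f"m\t{s}\t{s.count('1')}\t1\t{g * HARTREE_TO_KCAL:.10f}"
            f"\tkcal_mol\tx\n"
            for s, g in energies.items()
        )
        hart_rows = "".join(
            f"m\t{s}\t{s.count('1')}\t1\t{g:.10f}\thartree\tx\n"
            for s, g in energies.items()
        )
        t_kcal = FreeEnergyTable.read_tsv(io.StringIO(header + kcal_rows))
        t_hart = FreeEnergyTable.read_tsv(io.StringIO(header + hart_rows))
        ms = enumerate_microstates(["a", "b"], 2)
        edges = deprotonation_edges(ms)
        p1 = [p.pka for p in all_micro_pkas(t_kcal, edges, C)]
        p2 = [p.pka for p in all_micro_pkas(t_hart, edges, C)]
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_duplicate_records_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"molecule": "m", "microstate": "1", "conformer": 1, "G": 0.0},
                {"molecule": "m", "microstate": "1", "conformer": 1, "G": 1.0},
            ]
        )
        with pytest.raises(InputError, match="duplicate"):
            FreeEnergyTable(df, 1, 1)

    def test_tsv_roundtrip(self, tmp_path, interacting_table):
        path = tmp_path / "g.tsv"
        interacting_table.to_tsv(path)
        back = FreeEnergyTable.read_tsv(path)
        np.testing.assert_allclose(
            back.records["G"], interacting_table.records["G"], atol=1e-9
        )
        assert back.reference_charge == interacting_table.reference_charge


class TestAllMicroPkas:
    def test_single_site_equals_pair_pka(self):
        table = FreeEnergyTable.from_state_energies(
            {"1": -5.0, "0": 278.0}, 1
        )
        ms = enumerate_microstates(["s"], 1)
        (result,) = all_micro_pkas(table, deprotonation_edges(ms), C)
        assert result.pka == pytest.approx(micro_pka(-5.0, 278.0, C))

    def test_full_hypercube_count_and_order(self, tetra_model):
        table = surrogate_free_energies(tetra_model, C)
        ms = enumerate_microstates(tetra_model.site_labels, 4)
        edges = deprotonation_edges(ms)
        pkas = all_micro_pkas(table, edges, C)
        assert len(pkas) == 32
        assert [(p.donor, p.site) for p in pkas] == [
            (e.donor.id, e.site) for e in edges
        ]

    def test_matches_surrogate_closed_form(self, interacting_model):
        table = surrogate_free_energies(interacting_model, C)
        ms = enumerate_microstates(interacting_model.site_labels, 3)
        pkas = all_micro_pkas(table, deprotonation_edges(ms), C)
        assert len(pkas) == 12
        for p in pkas:
            occ = tuple(int(ch) for ch in p.donor)
            i = interacting_model.site_labels.index(p.site)
            assert p.pka == pytest.approx(
                closed_form_micro_pka(interacting_model, occ, i), abs=1e-9
            )

    def test_strict_mode_raises_on_missing_state(self, interacting_table):
        partial = FreeEnergyTable(
            interacting_table.records.query("microstate != '010'"), 3, 3
        )
        ms = enumerate_microstates(["a", "b", "c"], 3)
        edges = deprotonation_edges(ms)
        with pytest.raises(MissingStateError):
            all_micro_pkas(partial, edges, C, strict=True)
        with pytest.warns(UserWarning, match="010"):
            pkas = all_micro_pkas(partial, edges, C)
        assert len(pkas) == 12 - 3  # the three edges touching '010' skipped


class TestCycleClosure:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_squares_close_exactly(self, seed):
        """Around any 2-bit square the four microscopic pKa must cancel:
        energies are state functions."""
        rng = np.random.default_rng(seed)
        n = 4
        energies = random_state_energies(rng, n)
        table = FreeEnergyTable.from_state_energies(energies, n)
        ms = enumerate_microstates([f"s{i}" for i in range(n)], n)
        pka = {
            (p.donor, p.acceptor): p.pka
            for p in all_micro_pkas(table, deprotonation_edges(ms), C)
        }

        def clear(sid, i):
            return sid[:i] + "0" + sid[i + 1:]

        checked = 0
        for sid in energies:
            ones = [i for i, b in enumerate(sid) if b == "1"]
            for i, j in itertools.combinations(ones, 2):
                lhs = pka[(sid, clear(sid, i))] + pka[
                    (clear(sid, i), clear(clear(sid, i), j))
                ]
                rhs = pka[(sid, clear(sid, j))] + pka[
                    (clear(sid, j), clear(clear(sid, j), i))
                ]
                assert lhs == pytest.approx(rhs, abs=1e-9)
                checked += 1
        assert checked == 24  # C(4,2) squares x 4 top states... per top corner
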