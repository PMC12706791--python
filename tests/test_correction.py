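"""Boltzmann conformer averaging and empirical correction factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyranoshift.correction import (
    ConformerSet,
    CorrectionFactors,
    R_GAS,
    apply_corrections,
    boltzmann_average,
    correction_class,
    default_correction_factors,
    derive_correction_factors,
)
from pyranoshift.shift_data import CompoundEntry, ShiftRecord, ValidationError
from pyranoshift.synthetic_data import GeneratorConfig, generate_modeling_set


def entry(cid, rows, kind="experimental"):
    return CompoundEntry(
        id=cid,
        name="",
        subtype=None,
        shifts=tuple(ShiftRecord(l, s, c) for l, s, c in rows),
        kind=kind,
    )


class TestBoltzmannAverage:
    def test_single_conformer_is_identity(self):
        cs = ConformerSet(energies=(5.0,), shift_tables=({"C-1": 100.0},))
        assert boltzmann_average(cs)["C-1"] == pytest.approx(100.0)

    def test_equal_energies_give_plain_mean(self):
        cs = ConformerSet(energies=(2.0, 2.0), shift_tables=({"C-1": 100.0}, {"C-1": 102.0}))
        assert boltzmann_average(cs)["C-1"] == pytest.approx(101.0)

    def test_rt_ln2_gap_gives_two_thirds_one_third(self):
        # ΔE = RT·ln2 makes the higher conformer exactly half as populated
        gap_kj = R_GAS * 298.15 * math.log(2.0) / 1000.0
        cs = ConformerSet(
            energies=(0.0, gap_kj), shift_tables=({"C-1": 100.0}, {"C-1": 103.0})
        )
        assert boltzmann_average(cs)["C-1"] == pytest.approx(101.0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        energies=st.lists(st.floats(-20, 40, allow_nan=False), min_size=1, max_size=6),
        offset=st.floats(-500, 500, allow_nan=False),
    )
    def test_invariant_to_energy_offset_and_order(self, energies, offset):
        tables = tuple({"C-1": 90.0 + 3.0 * i} for i in range(len(energies)))
        base = boltzmann_average(ConformerSet(tuple(energies), tables))
        shifted = boltzmann_average(
            ConformerSet(tuple(e + offset for e in energies), tables)
        )
        perm = np.random.RandomState(0).permutation(len(energies))
        permuted = boltzmann_average(
            ConformerSet(
                tuple(energies[i] for i in perm), tuple(tables[i] for i in perm)
            )
        )
        assert base["C-1"] == pytest.approx(shifted["C-1"], abs=1e-9)
        assert base["C-1"] == pytest.approx(permuted["C-1"], abs=1e-9)

    def test_high_temperature_limit_is_unweighted_mean(self):
        cs = ConformerSet(
            energies=(0.0, 30.0),
            shift_tables=({"C-1": 100.0}, {"C-1": 104.0}),
            temperature=1.0e9,
        )
        assert boltzmann_average(cs)["C-1"] == pytest.approx(102.0, abs=1e-4)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValidationError):
            ConformerSet(energies=(0.0, 1.0), shift_tables=({"C-1": 100.0}, {"C-2": 100.0}))


class TestCorrectionClass:
    def test_c1_and_c8_pool_together(self):
        assert correction_class(ShiftRecord("C-1", 160.0, "core_Cq")) == "C1_C8"
        assert correction_class(ShiftRecord("C-8", 110.0, "core_CH")) == "C1_C8"
        assert (
            correction_class(ShiftRecord("C-1'", 116.0, "pyran_olefinic_1p"))
            == "pyran_olefinic_1p"
        )


class TestDeriveFactors:
    def test_exact_recovery_noise_free(self):
        exp = entry("e", [("C-1", 160.0, "core_Cq"), ("C-8", 110.0, "core_CH")])
        calc = entry(
            "c", [("C-1", 162.9, "core_Cq"), ("C-8", 112.9, "core_CH")], kind="calculated"
        )
        factors = derive_correction_factors([(exp, calc)], classes=("C1_C8",))
        assert factors.per_class["C1_C8"] == pytest.approx(-2.9)
        assert factors.n_per_class["C1_C8"] == 2

    def test_empty_class_omitted_with_warning(self):
        exp = entry("e", [("C-1", 160.0, "core_Cq")])
        calc = entry("c", [("C-1", 161.0, "core_Cq")], kind="calculated")
        with pytest.warns(UserWarning):
            factors = derive_correction_factors(
                [(exp, calc)], classes=("C1_C8", "pyran_olefinic_1p")
            )
        assert "pyran_olefinic_1p" not in factors.per_class

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift_by=st.floats(-10, 10, allow_nan=False))
    def test_location_equivariance(self, shift_by):
        exp = entry("e", [("C-1", 160.0, "core_Cq"), ("C-8", 110.3, "core_CH")])
        calc = entry("c", [("C-1", 161.7, "core_Cq"), ("C-8", 112.1, "core_CH")], kind="calculated")
        moved = entry(
            "c2",
            [("C-1", 161.7 + shift_by, "core_Cq"), ("C-8", 112.1 + shift_by, "core_CH")],
            kind="calculated",
        )
        f0 = derive_correction_factors([(exp, calc)], classes=("C1_C8",))
        f1 = derive_correction_factors([(exp, moved)], classes=("C1_C8",))
        assert f1.per_class["C1_C8"] == pytest.approx(f0.per_class["C1_C8"] - shift_by, abs=1e-9)

    def test_apply_after_derive_zeroes_class_means(self):
        config = GeneratorConfig(n_compounds=12, calc_noise_sd=1.0, seed=5)
        pairs = generate_modeling_set(config)
        factors = derive_correction_factors(pairs)
        residuals = {cls: [] for cls in factors.per_class}
        for exp, calc in pairs:
            corrected = apply_corrections(calc, factors)
            calc_map = {r.label: r for r in corrected.shifts}
            for rec in exp.shifts:
                cls = correction_class(rec)
                if cls in residuals and rec.label in calc_map:
                    residuals[cls].append(rec.shift - calc_map[rec.label].shift)
        for cls, vals in residuals.items():
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_recovery_close_to_injected_offsets(self):
        config = GeneratorConfig(n_compounds=76, calc_noise_sd=1.0, seed=42)
        factors = derive_correction_factors(generate_modeling_set(config))
        assert factors.per_class["C1_C8"] == pytest.approx(-2.9, abs=3 * 1.0 / math.sqrt(76))
        assert factors.per_class["pyran_olefinic_1p"] == pytest.approx(-3.7, abs=3 / math.sqrt(76))
        assert factors.per_class["pyran_olefinic_2p"] == pytest.approx(2.8, abs=3 / math.sqrt(76))


class TestApplyCorrections:
    def test_published_offset_arithmetic(self):
        calc = entry(
            "c",
            [("C-1", 160.0, "core_Cq"), ("C-2'", 128.0, "pyran_olefinic_2p"), ("C-5", 100.0, "core_CH")],
            kind="calculated",
        )
        corrected = apply_corrections(calc, default_correction_factors())
        shifts = {r.label: r.shift for r in corrected.shifts}
        assert shifts["C-1"] == pytest.approx(157.1)
        assert shifts["C-2'"] == pytest.approx(130.8)
        assert shifts["C-5"] == pytest.approx(100.0)  # untouched class passes through
        assert calc.shift_map()["C-1"][0] == pytest.approx(160.0)  # input not mutated

    def test_empty_factors_are_identity(self):
        calc = entry("c", [("C-1", 160.0, "core_Cq")], kind="calculated")
        assert apply_corrections(calc, CorrectionFactors(per_class={})) == calc
        assert apply_corrections(calc, None) == calc


class TestFactorSerialization:
    def test_json_roundtrip(self):
        f = CorrectionFactors(
            per_class={"C1_C8": -2.9, "pyran_olefinic_1p": -3.7},
            n_per_class={"C1_C8": 152, "pyran_olefinic_1p": 76},
            sd_per_class={"C1_C8": 0.9, "pyran_olefinic_1p": 1.1},
            scope="gathered",
        )
        assert CorrectionFactors.from_json(f.to_json()) == f
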