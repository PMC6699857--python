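"""Compound-table assembly, resolve step and the end-to-end pipeline."""

import pandas as pd
import pytest

from chcid import (
    CompoundRecord,
    SimSpectrumParams,
    assemble_table,
    determine_parent,
    make_reference_table,
    make_structure,
    nominal_mass,
    resolve_compound,
    run_pipeline,
    simulate_spectrum,
    generate_dataset,
)
from chcid.errors import FormulaError, InsufficientLadderError
from chcid.spectra import ParentAssignment


class TestNominalMass:
    @pytest.mark.parametrize("formula,expected", [
        ("C30H62", 422),
        ("C15H32", 212),
        ("C35H72", 492),
        ("C18H36O", 268),
        ("C18H32O2", 280),
    ])
    def test_values(self, formula, expected):
        assert nominal_mass(formula) == expected

    @pytest.mark.parametrize("bad", ["", "XYZ", "C30H62N"])
    def test_rejects(self, bad):
        with pytest.raises(FormulaError):
            nominal_mass(bad)


class TestAssembleTable:
    def test_empty_input(self):
        table = assemble_table([])
        assert len(table) == 0

    def test_coelution_flag(self):
        recs = [
            CompoundRecord(30.000, 366, "C26H54", "Hexacosane", 2600, "A"),
            CompoundRecord(30.001, 380, "C27H56", "Heptacosane", 2700, "B"),
            CompoundRecord(31.500, 394, "C28H58", "Octacosane", 2800, "C"),
        ]
        table = assemble_table(recs)
        flagged = table[table["flags"].str.contains("possible-coelution")]
        assert set(flagged["peak_id"]) == {"A", "B"}

    def test_mw_formula_mismatch_flagged_not_raised(self):
        recs = [CompoundRecord(30.0, 400, "C26H54", "Hexacosane", 2600, "A")]
        table = assemble_table(recs)
        assert "mw-formula-mismatch" in table["flags"].iloc[0]

    def test_sorted_by_retention_time(self):
        recs = [
            CompoundRecord(31.5, 380, "C27H56", "Heptacosane", 2700, "B"),
            CompoundRecord(30.0, 366, "C26H54", "Hexacosane", 2600, "A"),
        ]
        table = assemble_table(recs)
        assert list(table["peak_id"]) == ["A", "B"]


@pytest.fixture(scope="module")
def curves():
    from chcid import build_curves
    return build_curves(make_reference_table())


class TestResolveCompound:

    def test_monomethyl_worked_example(self, curves):
        rec = resolve_compound(
            ParentAssignment(422, "C30H62", 30, 0), [141, 309], 2938.0, curves)
        assert (rec.nominal_mw, rec.molecular_formula, rec.structure_name) == \
            (422, "C30H62", "9-methylnonacosane")

    def test_linear_alkane(self, curves):
        rec = resolve_compound(ParentAssignment(366, "C26H54", 26, 0), [],
                               2600.0, curves)
        assert rec.structure_name == "Hexacosane" and not rec.flags

    def test_alkene_gets_asterisk_name(self, curves):
        rec = resolve_compound(ParentAssignment(322, "C23H46", 23, 1), [],
                               2279.0, curves)
        assert rec.structure_name == "*-tricosene"
        assert "double-bond-position-unassigned" in rec.flags

    def test_ion_evidence_overrides_curve_hint(self, curves):
        # RI says linear (3000) but the spectrum shows a clean branch-ion
        # pair; the ions win, with a conflict flag.  Without the RI vote the
        # pair {141, 309} is genuinely isobaric between 9-methylnonacosane
        # and 9,20-dimethyloctacosane, so the name carries the asterisk.
        rec = resolve_compound(ParentAssignment(422, "C30H62", 30, 0),
                               [141, 309], 3000.0, curves)
        assert rec.structure_name == "*-methylnonacosane"
        assert rec.annotation == "possibly 9-"
        assert "branch-count-conflict" in rec.flags

    def test_correct_curve_hint_resolves_isobaric_tie(self, curves):
        # with the RI voting monomethyl, the same ion pair resolves cleanly
        rec = resolve_compound(ParentAssignment(422, "C30H62", 30, 0),
                               [141, 309], 2938.0, curves)
        assert rec.structure_name == "9-methylnonacosane"
        assert "branch-count-conflict" not in rec.flags

    def test_errors_become_flags(self, curves):
        rec = resolve_compound(ParentAssignment(423, None, None, None, True),
                               [], 2950.0, curves)
        assert rec.structure_name == "unidentified"
        assert "no-molecular-series" in rec.flags


class TestRunPipeline:
    def test_noise_free_closure(self):
        """50 simulated compounds with 0-2 branches and no noise are all
        recovered exactly (name, MW, formula)."""
        spectra, _, ladder, truth = generate_dataset(
            50, (0, 2), seed=3, params=SimSpectrumParams(noise_sd=0.0))
        table, log = run_pipeline(
            spectra, list(zip(ladder["carbon_number"],
                              ladder["retention_time_min"])),
            make_reference_table())
        merged = table.merge(truth, on="peak_id", suffixes=("", "_true"))
        assert len(merged) == 50
        assert (merged["structure"] == merged["structure_true"]).all()
        assert (merged["mw"] == merged["mw_true"]).all()
        assert (merged["formula"] == merged["formula_true"]).all()
        assert len(log) == 50

    def test_determinism_byte_identical(self, tmp_path):
        from chcid.io import write_compound_table
        spectra, _, ladder, _ = generate_dataset(10, (0, 1), seed=9)
        args = (spectra, list(zip(ladder["carbon_number"],
                                  ladder["retention_time_min"])),
                make_reference_table())
        for name in ("a.csv", "b.csv"):
            table, _ = run_pipeline(*args)
            write_compound_table(table, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_missing_ladder_is_fatal(self):
        spectra, _, _, _ = generate_dataset(2, (0, 0), seed=1)
        with pytest.raises(InsufficientLadderError):
            run_pipeline(spectra, [], make_reference_table())

    def test_ri_computed_even_without_reference(self):
        spectra, _, ladder, truth = generate_dataset(
            3, (0, 0), seed=11, params=SimSpectrumParams(noise_sd=0.0))
        table, _ = run_pipeline(spectra, list(zip(ladder["carbon_number"],
                                                  ladder["retention_time_min"])))
        merged = table.merge(truth, on="peak_id", suffixes=("", "_true"))
        assert (merged["ri"].astype(float)
                == merged["ri_true"].round()).all()


def test_full_synthetic_spectrum_resolves_to_worked_example():
    from chcid import build_curves, detect_enhanced, extract_envelope, fit_decay

    spec = simulate_spectrum(make_structure(29, [9]),
                             SimSpectrumParams(noise_sd=0.0))
    parent = determine_parent(spec)
    fit = fit_decay(extract_envelope(spec, parent), parent_mz=parent.parent_mz)
    rec = resolve_compound(parent, detect_enhanced(fit), 2938.0,
                           build_curves(make_reference_table()))
    assert rec.structure_name == "9-methylnonacosane"
    assert rec.nominal_mw == 422 and rec.molecular_formula == "C30H62"
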