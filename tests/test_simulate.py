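"""The Abraham-equation GC simulator: parameters, ladder, Kovats indices."""

import numpy as np
import pytest

from gcri.chem import parse_molecule
from gcri.phases import NON_POLAR, POLAR
from gcri.simulate import (AbrahamAnalyte, AbrahamPhase, AlkaneLadder,
                           SimulatorConfigError, abraham_parameters,
                           build_corpus, default_phases, generate_library,
                           kovats_ri, log_k, make_ladder, make_linear_phase)


def _analyte(smiles, seed=0, **overrides):
    mol = parse_molecule(smiles)
    params = abraham_parameters(mol, seed)
    params.update(overrides)
    return AbrahamAnalyte(molecule=mol, **params)


class TestLogK:
    def test_zero_analyte_gives_phase_intercept(self):
        phase = AbrahamPhase("P", c=-0.7, e=0.2, s=0.3, a=0.4, b=0.1, l=1.0)
        analyte = _analyte("CC(C)C", E=0, S=0, A=0, B=0, L=1e-9)
        assert log_k(analyte, phase) == pytest.approx(-0.7)

    def test_single_term(self):
        phase = AbrahamPhase("P", c=-1.0, e=0.2, s=0, a=0, b=0, l=1e-12)
        analyte = _analyte("CC(C)C", E=1.0, S=0, A=0, B=0, L=1.0)
        assert log_k(analyte, phase) == pytest.approx(-0.8)

    def test_linearity_in_analyte_parameters(self):
        phase = AbrahamPhase("P", c=0.1, e=0.25, s=0.5, a=0.2, b=0.1, l=0.9)
        one = _analyte("CC(C)C", E=1.0)
        two = _analyte("CC(C)C", E=2.0)
        assert log_k(two, phase) - log_k(one, phase) == pytest.approx(0.25)


class TestLibrary:
    def test_fixed_seed_reproducible(self):
        a = generate_library(30, seed=5)
        b = generate_library(30, seed=5)
        assert [x.molecule.canonical_smiles for x in a] == \
            [x.molecule.canonical_smiles for x in b]
        assert [(x.E, x.S, x.A, x.B, x.L) for x in a] == \
            [(x.E, x.S, x.A, x.B, x.L) for x in b]

    def test_homolog_size_ordering(self):
        ethanol = abraham_parameters(parse_molecule("CCO"), seed=1)
        propanol = abraham_parameters(parse_molecule("CCCO"), seed=1)
        assert propanol["L"] > ethanol["L"]

    def test_donor_free_analytes_have_zero_A(self):
        assert abraham_parameters(parse_molecule("CC(C)CC"), seed=3)["A"] == 0.0
        assert abraham_parameters(parse_molecule("CCOCC"), seed=3)["A"] == 0.0

    def test_no_n_alkanes_in_library(self):
        from gcri.chem import is_n_alkane

        assert not any(is_n_alkane(a.molecule) for a in generate_library(80, seed=0))


class TestKovats:
    phase = AbrahamPhase("P", c=-0.2, e=0, s=0, a=0, b=0, l=1.0)

    def test_ladder_member_is_anchored(self):
        ladder = make_ladder(self.phase, 5, 40)
        # an analyte with exactly n-octane's log k indexes at 800
        analyte = _analyte("CC(C)C", E=0, S=0, A=0, B=0, L=0.52 * 8)
        result = kovats_ri(analyte, self.phase, ladder)
        assert result.ri == pytest.approx(800.0)
        assert not result.extrapolated

    def test_midpoint_between_bracketing_alkanes(self):
        ladder = make_ladder(self.phase, 5, 40)
        analyte = _analyte("CC(C)C", E=0, S=0, A=0, B=0, L=0.52 * 8.5)
        assert kovats_ri(analyte, self.phase, ladder).ri == pytest.approx(850.0)

    def test_c10_member_indexes_at_1000(self):
        ladder = make_ladder(self.phase, 5, 40)
        analyte = _analyte("CC(C)C", E=0, S=0, A=0, B=0, L=0.52 * 10)
        assert kovats_ri(analyte, self.phase, ladder).ri == pytest.approx(1000.0)

    def test_extrapolation_is_flagged(self):
        ladder = make_ladder(self.phase, 8, 12)
        low = _analyte("CC(C)C", E=0, S=0, A=0, B=0, L=0.52 * 5)
        result = kovats_ri(low, self.phase, ladder)
        assert result.extrapolated
        assert result.ri == pytest.approx(500.0)  # exact on a linear ladder

    def test_non_monotone_ladder_rejected(self):
        with pytest.raises(SimulatorConfigError):
            AlkaneLadder("P", carbons=np.array([5, 6, 7]),
                         logk=np.array([1.0, 0.9, 1.2]))


class TestCorpus:
    def test_noiseless_records_equal_truth(self):
        library = generate_library(15, seed=2)
        records, truth = build_corpus(library, default_phases()[:2], seed=3, noise=False)
        by_key = {(r.compound_key, r.phase): r.ri for r in records}
        for row in truth.itertuples():
            assert by_key[(row.compound_key, row.phase)] == pytest.approx(row.ri_true)

    def test_bit_reproducible(self):
        library = generate_library(10, seed=2)
        a, _ = build_corpus(library, default_phases()[:3], seed=7)
        b, _ = build_corpus(library, default_phases()[:3], seed=7)
        assert [r.ri for r in a] == [r.ri for r in b]

    def test_noise_magnitude_half_normal(self):
        # mean |noise| of N(0, sd) is sd * sqrt(2/pi); check at 10,000 draws
        library = generate_library(10, seed=2)
        phase = AbrahamPhase("P", c=-0.2, e=0, s=0, a=0, b=0, l=1.0, ri_noise_sd=10.0)
        records, truth = build_corpus(library, [phase], seed=11, replicates=1000)
        truth_map = dict(zip(truth.compound_key, truth.ri_true))
        deviations = np.abs([r.ri - truth_map[r.compound_key] for r in records])
        expected = 10.0 * np.sqrt(2 / np.pi)
        assert deviations.mean() == pytest.approx(expected, rel=0.05)

    def test_family_labels_follow_phase(self):
        library = generate_library(5, seed=2)
        records, _ = build_corpus(library, default_phases(), seed=3)
        families = {r.phase: r.family for r in records}
        assert families["DB-1"] == NON_POLAR and families["DB-WAX"] == POLAR


class TestLinearPhase:
    def test_single_base_identity(self):
        base = default_phases()[0]
        combo = make_linear_phase([base], [1.0], name="copy")
        np.testing.assert_allclose(combo.vector, base.vector)

    def test_log_k_linearity(self):
        p1, p2 = default_phases()[0], default_phases()[5]
        mix = make_linear_phase([p1, p2], [0.5, 0.5], name="mix")
        analyte = _analyte("CCO")
        assert log_k(analyte, mix) == pytest.approx(
            0.5 * log_k(analyte, p1) + 0.5 * log_k(analyte, p2))

    def test_empty_bases_rejected(self):
        with pytest.raises(ValueError):
            make_linear_phase([], [], name="empty")


def test_polarity_ordering_alcohol_vs_alkylbenzene():
    """A phase with large (s,a,b) shifts a donor analyte's RI up far more
    than an alkylbenzene's, relative to a non-polar phase."""
    phases = {p.name: p for p in default_phases()}
    nonpolar, polar = phases["DB-1"], phases["DB-WAX"]
    shifts = {}
    for name, smiles in (("alcohol", "CCCCCO"), ("aromatic", "CCc1ccccc1")):
        analyte = _analyte(smiles, seed=5)
        ri_np = kovats_ri(analyte, nonpolar, make_ladder(nonpolar)).ri
        ri_p = kovats_ri(analyte, polar, make_ladder(polar)).ri
        shifts[name] = ri_p - ri_np
    assert shifts["alcohol"] > shifts["aromatic"] > 0
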