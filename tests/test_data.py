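"""Admission filtering, compound-based splits and the metric suite."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcri.chem import parse_molecule
from gcri.data import (AdmissionConfig, RetentionRecord, admit, admit_molecule,
                       exclude_compounds, iter_train_test, kfold, load_records,
                       metrics, save_records)


def _record(smiles, phase="DB-5", family="non-polar", ri=800.0):
    return RetentionRecord(molecule=parse_molecule(smiles), phase=phase,
                           family=family, ri=ri)


class TestAdmission:
    def test_element_whitelist(self):
        # selenomethionine carries selenium, outside the whitelist
        reason = admit_molecule(parse_molecule("C[Se]CCC(N)C(=O)O"))
        assert reason is not None and "Se" in reason

    def test_n_alkane_rule(self):
        assert admit_molecule(parse_molecule("CCCCCCCCCC")) == "n-alkane"

    def test_size_cap(self):
        big = parse_molecule("C(=O)" + "C" * 120)
        assert "heavy atoms" in admit_molecule(big)

    def test_toluene_admitted(self):
        assert admit_molecule(parse_molecule("Cc1ccccc1")) is None

    def test_rejections_logged_not_fatal(self):
        records = [_record("Cc1ccccc1"), _record("CCCCCCCCCC")]
        admitted, rejections = admit(records)
        assert len(admitted) == 1 and len(rejections) == 1
        assert rejections[0][1] == "n-alkane"

    def test_rules_are_configurable(self):
        config = AdmissionConfig(reject_n_alkanes=False)
        assert admit_molecule(parse_molecule("CCCCCC"), config) is None


class TestCompoundExclusion:
    def test_stereoisomer_excluded(self):
        train = [_record("CC(=C)[C@@H]1CCC(C)=CC1")]   # one limonene enantiomer
        test = [_record("CC(=C)[C@H]1CCC(C)=CC1")]     # the other
        assert exclude_compounds(train, test) == []

    def test_disjoint_sets_unchanged(self):
        train = [_record("CCO"), _record("CCCO")]
        test = [_record("CCCCO")]
        assert exclude_compounds(train, test) == train

    def test_postcondition_zero_overlap(self):
        train = [_record(s) for s in ("CCO", "CCCO", "CCCCO", "CC(C)O")]
        test = [_record(s) for s in ("CCCO", "CC(C)O")]
        kept = exclude_compounds(train, test)
        assert not {r.compound_key for r in kept} & {r.compound_key for r in test}


class TestKFold:
    def _records(self, n=100):
        out = []
        for i in range(n):
            smiles = "O" + "C" * (i % 17 + 1) + ("N" if i % 2 else "")
            out.append(_record(smiles, ri=500 + i))
            out.append(_record(smiles, phase="DB-1", ri=510 + i))  # replicate entry
        return out

    def test_fold_sizes_balanced(self):
        folds = kfold(self._records(100), k=5, seed=0)
        sizes = [len({r.compound_key for r in f}) for f in folds]
        assert sum(sizes) == len({r.compound_key for r in self._records(100)})
        assert max(sizes) - min(sizes) <= 1

    def test_records_follow_their_compound(self):
        folds = kfold(self._records(60), k=5, seed=1)
        keysets = [{r.compound_key for r in f} for f in folds]
        for i in range(len(keysets)):
            for j in range(i + 1, len(keysets)):
                assert not keysets[i] & keysets[j]

    def test_deterministic(self):
        a = kfold(self._records(40), k=4, seed=9)
        b = kfold(self._records(40), k=4, seed=9)
        assert [[r.compound_key for r in f] for f in a] == \
            [[r.compound_key for r in f] for f in b]

    def test_train_test_iteration_covers_all(self):
        records = self._records(20)
        for train, test in iter_train_test(kfold(records, k=4, seed=0)):
            assert len(train) + len(test) == len(records)
            assert not {r.compound_key for r in train} & {r.compound_key for r in test}

    def test_too_few_compounds(self):
        with pytest.raises(ValueError):
            kfold([_record("CCO")], k=2, seed=0)


class TestMetrics:
    def test_hand_computed_example(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant refs: r2 undefined
            report = metrics([1010, 990, 1030], [1000, 1000, 1000])
        assert report.mae == pytest.approx(16.6667, abs=1e-3)
        assert report.mdae == pytest.approx(10.0)
        assert report.rmse == pytest.approx(19.1485, abs=1e-3)
        assert report.mpe == pytest.approx(1.6667, abs=1e-3)
        assert report.mdpe == pytest.approx(1.0)

    def test_perfect_predictions(self):
        report = metrics([500.0, 800.0, 1200.0], [500.0, 800.0, 1200.0])
        assert report.mae == report.mdae == report.rmse == 0.0
        assert report.r2 == 1.0
        assert report.coverage90 == 0.0

    def test_constant_references_r2_undefined(self):
        with pytest.warns(UserWarning, match="r2 undefined"):
            report = metrics([990, 1010], [1000, 1000])
        assert np.isnan(report.r2)

    def test_coverage90_semantics(self):
        errors = np.arange(1.0, 101.0)  # |delta| = 1..100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = metrics(1000 + errors, np.full(100, 1000.0))
        assert report.coverage90 == pytest.approx(np.quantile(errors, 0.9))

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.floats(100, 4000), st.floats(100, 4000)),
                    min_size=2, max_size=40))
    def test_rmse_dominates_mae_and_permutation_invariance(self, pairs):
        preds = np.array([p for p, _ in pairs])
        refs = np.array([r for _, r in pairs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = metrics(preds, refs)
            perm = np.random.default_rng(0).permutation(len(pairs))
            shuffled = metrics(preds[perm], refs[perm])
        assert report.rmse >= report.mae - 1e-9
        for field in ("mae", "mdae", "rmse", "mpe", "mdpe", "coverage90"):
            assert getattr(report, field) == pytest.approx(getattr(shuffled, field))

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 300), min_size=2, max_size=30),
           st.floats(301, 1000))
    def test_coverage90_monotone_in_added_error(self, errors, bigger):
        refs = np.full(len(errors), 1000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = metrics(refs + np.array(errors), refs)
            grown = metrics(np.append(refs, 1000.0) + np.array(errors + [bigger]),
                            np.append(refs, 1000.0))
        assert grown.coverage90 >= base.coverage90 - 1e-9


def test_record_table_round_trip(tmp_path):
    records = [_record("CCO", ri=430.0), _record("CCCO", "DB-WAX", "polar", 990.0)]
    path = tmp_path / "records.csv"
    save_records(records, path)
    loaded, rejected = load_records(path)
    assert not rejected
    assert [(r.compound_key, r.phase, r.family, r.ri) for r in loaded] == \
        [(r.compound_key, r.phase, r.family, r.ri) for r in records]


def test_load_records_logs_parse_failures(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("smiles,phase,family,ri\nCCO,DB-5,non-polar,430\n"
                    "xx(,DB-5,non-polar,500\n")
    loaded, rejected = load_records(path)
    assert len(loaded) == 1
    assert rejected == [("xx(", "parse failure")]
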