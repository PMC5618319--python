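"""Adduct arithmetic and exact-mass database matching."""

import numpy as np
import pytest

from pcaplanes import (
    KNOWN_ADDUCTS,
    AdductRule,
    CompoundDB,
    FeatureKey,
    StrainReport,
    UniqueFeatureRecord,
    annotate_report,
    ion_mz,
    match_mass,
    neutral_mass,
)

MH = KNOWN_ADDUCTS["[M+H]+"]


def linear_scan(mz, db, adducts, tol_ppm):
    """Independent all-pairs oracle for match_mass."""
    hits = []
    for ai, adduct in enumerate(adducts):
        M = mz * adduct.charge - adduct.mass_shift
        if M <= 0:
            continue
        for name, mass in zip(db.names, db.masses):
            ppm = (M - mass) / mass * 1e6
            if abs(ppm) <= tol_ppm:
                hits.append((abs(ppm), ai, name, adduct.label, ppm))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return [(n, l, p) for _, _, n, l, p in hits]


class TestNeutralMass:
    def test_protonated_ion_hand_arithmetic(self):
        assert neutral_mass(901.4205, MH) == pytest.approx(900.4132, abs=5e-5)

    def test_bare_proton_rejected(self):
        with pytest.raises(ValueError):
            neutral_mass(1.007276, MH)

    def test_sodium_adduct_round_trip(self):
        na = KNOWN_ADDUCTS["[M+Na]+"]
        assert ion_mz(100.0, na) == pytest.approx(122.989218, abs=1e-9)
        assert neutral_mass(122.989218, na) == pytest.approx(100.0, abs=1e-9)

    def test_doubly_charged_round_trip(self):
        d = KNOWN_ADDUCTS["[M+2H]2+"]
        M = 900.4132
        assert neutral_mass(ion_mz(M, d), d) == pytest.approx(M, abs=1e-9)

    def test_round_trip_error_below_nano_dalton(self, rng):
        for adduct in KNOWN_ADDUCTS.values():
            for M in rng.uniform(150, 1500, 50):
                assert abs(neutral_mass(ion_mz(M, adduct), adduct) - M) < 1e-9

    def test_charge_must_be_positive(self):
        with pytest.raises(ValueError):
            AdductRule("bad", 1.0, 0)


class TestMatchMass:
    def test_known_compound_matches_near_zero_ppm(self):
        db = CompoundDB(names=["knownomycin"], masses=[900.413224])
        res = match_mass(901.4205, db, [MH], tol_ppm=4)
        assert not res.novel
        name, label, ppm = res.best()
        assert name == "knownomycin" and label == "[M+H]+"
        assert abs(ppm) < 0.01

    def test_mass_outside_tolerance_is_novel(self):
        # 900.4200 is ~7.5 ppm from the query's neutral mass 900.413224
        db = CompoundDB(names=["decoy"], masses=[900.4200])
        assert match_mass(901.4205, db, [MH], tol_ppm=4).novel

    def test_widened_tolerance_recovers_match(self):
        db = CompoundDB(names=["decoy"], masses=[900.4200])
        res = match_mass(901.4205, db, [MH], tol_ppm=10)
        assert not res.novel

    def test_match_set_monotone_in_tolerance(self, rng):
        db = CompoundDB(names=[f"c{i}" for i in range(500)],
                        masses=np.sort(rng.uniform(150, 1500, 500)))
        adducts = list(KNOWN_ADDUCTS.values())
        for mz in rng.uniform(150, 1500, 20):
            prev = set()
            for tol in (1, 4, 5, 10, 50):
                cur = {(n, l) for n, l, _ in match_mass(mz, db, adducts, tol).matches}
                assert prev <= cur
                prev = cur

    def test_binary_search_equals_linear_scan(self, rng):
        db = CompoundDB(names=[f"c{i}" for i in range(1000)],
                        masses=rng.uniform(150, 1500, 1000))
        adducts = list(KNOWN_ADDUCTS.values())
        queries = list(rng.uniform(150, 1500, 50)) + [ion_mz(m, MH) for m in db.masses[:20]]
        for mz in queries:
            for tol in (1, 5, 100):
                got = match_mass(mz, db, adducts, tol).matches
                assert got == linear_scan(mz, db, adducts, tol)

    def test_db_round_trip_recovers_entry(self, rng):
        db = CompoundDB(names=[f"c{i}" for i in range(50)],
                        masses=rng.uniform(150, 1500, 50))
        for name, mass in zip(db.names, db.masses):
            for adduct in KNOWN_ADDUCTS.values():
                res = match_mass(ion_mz(mass, adduct), db, [adduct], tol_ppm=0.001)
                assert (name, adduct.label) in {(n, l) for n, l, _ in res.matches}

    def test_empty_db_flags_novel_with_warning(self):
        db = CompoundDB(names=[], masses=[])
        with pytest.warns(UserWarning, match="empty"):
            assert match_mass(500.0, db).novel


class TestCompoundDB:
    def test_from_csv_and_sorting(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text("name,monoisotopic_mass,formula\nb,900.4132,C47H56N8O9\na,300.1,\n")
        db = CompoundDB.from_csv(p)
        assert list(db.masses) == sorted(db.masses)
        assert db.names == ["a", "b"]
        assert db.formulas == [None, "C47H56N8O9"]

    def test_missing_mass_column_rejected(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text("name,weight\nx,1.0\n")
        with pytest.raises(ValueError, match="monoisotopic_mass"):
            CompoundDB.from_csv(p)


class TestAnnotateReport:
    def _report(self, mzs):
        records = [
            UniqueFeatureRecord(
                feature=FeatureKey(rt=5.0, mz=mz), strain_id="A", plane=(13, 15),
                distance=1.0 / (k + 1), intensity=100.0, rank=k + 1,
            )
            for k, mz in enumerate(mzs)
        ]
        return StrainReport(strain_id="A", plane=(13, 15), records=records)

    def test_unmatched_fragment_flagged_novel(self):
        """A fragment mass with no compatible database entry signals novelty."""
        db = CompoundDB(names=["x"], masses=[500.0])
        out = annotate_report(self._report([760.2949]), db, tol_ppm=5)
        assert out.records[0].novel is True
        assert out.records[0].match_name is None

    def test_match_annotated_without_reordering(self):
        db = CompoundDB(names=["knownomycin"], masses=[900.413224])
        out = annotate_report(self._report([760.2949, 901.4205]), db, tol_ppm=5)
        assert [r.feature.mz for r in out.records] == [760.2949, 901.4205]
        assert out.records[0].novel and not out.records[1].novel
        assert out.records[1].match_name == "knownomycin"

    def test_empty_report_unchanged(self):
        db = CompoundDB(names=["x"], masses=[500.0])
        out = annotate_report(self._report([]), db)
        assert out.records == []

    def test_annotation_matches_all_pairs_oracle(self, rng):
        db = CompoundDB(names=[f"c{i}" for i in range(2000)],
                        masses=rng.uniform(150, 1500, 2000))
        mzs = rng.uniform(150, 1500, 30)
        out = annotate_report(self._report(sorted(mzs)), db, list(KNOWN_ADDUCTS.values()), 5)
        for rec in out.records:
            oracle = linear_scan(rec.feature.mz, db, list(KNOWN_ADDUCTS.values()), 5)
            if oracle:
                assert (rec.match_name, rec.match_adduct, rec.match_ppm) == oracle[0]
                assert rec.novel is False
            else:
                assert rec.novel is True
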