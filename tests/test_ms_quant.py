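"""EIC extraction, integration, isobaric apportionment, relative ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histoptm.ms_quant import (
    Chromatogram,
    apportion_isobaric,
    extract_ion_chromatogram,
    integrate_area,
    relative_ratios,
)

from conftest import random_area_table
from oracles import eic_oracle, trapezoid_oracle


def make_spectra(rows):
    return pd.DataFrame(rows, columns=["rt", "mz", "intensity"])


class TestEIC:
    def test_20ppm_away_centroid_excluded(self):
        spectra = make_spectra([(1.0, 500.0000, 10.0), (1.0, 500.0100, 20.0)])
        eic = extract_ion_chromatogram(spectra, 500.0, ppm_tol=10.0)
        assert eic.intensity.tolist() == [10.0]

    def test_boundary_exactly_10ppm_is_inclusive(self):
        mz = 500.0 + 0.005  # exactly +10 ppm of target 500
        spectra = make_spectra([(1.0, mz, 7.0)])
        eic = extract_ion_chromatogram(spectra, 500.0, ppm_tol=10.0)
        assert eic.intensity.tolist() == [7.0]

    def test_unmatched_scans_contribute_zero(self):
        spectra = make_spectra([(1.0, 500.0, 5.0), (2.0, 900.0, 5.0)])
        eic = extract_ion_chromatogram(spectra, 500.0, 10.0)
        assert eic.rt.tolist() == [1.0, 2.0]
        assert eic.intensity.tolist() == [5.0, 0.0]

    def test_matches_brute_force_oracle_on_random_spectra(self, rng):
        for _ in range(25):
            n = rng.integers(5, 80)
            rows = list(
                zip(
                    np.round(rng.uniform(0, 10, n), 2),
                    rng.uniform(400, 401, n),
                    rng.uniform(0, 1e5, n),
                )
            )
            spectra = make_spectra(rows).sort_values("rt")
            target = float(rng.uniform(400, 401))
            eic = extract_ion_chromatogram(spectra, target, 10.0)
            expected = eic_oracle(rows, target, 10.0)
            got = dict(zip(eic.rt, eic.intensity))
            assert got.keys() == expected.keys()
            for rt in expected:
                assert got[rt] == pytest.approx(expected[rt], rel=1e-12)

    @given(st.floats(min_value=1.0, max_value=50.0), st.floats(min_value=1.0, max_value=50.0))
    @settings(max_examples=30, deadline=None)
    def test_widening_tolerance_never_loses_intensity(self, tol1, tol2):
        rng = np.random.default_rng(99)
        n = 50
        spectra = make_spectra(
            list(zip(np.repeat(np.arange(5), 10), rng.uniform(499.9, 500.1, n),
                     rng.uniform(0, 100, n)))
        )
        lo, hi = sorted((tol1, tol2))
        narrow = extract_ion_chromatogram(spectra, 500.0, lo)
        wide = extract_ion_chromatogram(spectra, 500.0, hi)
        assert (wide.intensity >= narrow.intensity - 1e-12).all()

    def test_empty_spectra_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_ion_chromatogram(make_spectra([]), 500.0, 10.0)


class TestIntegration:
    def test_constant_trace_rectangle(self):
        rt = np.linspace(0, 1, 21)
        c = Chromatogram(500.0, 10.0, rt, np.full(21, 100.0))
        assert integrate_area(c, (0.0, 1.0)) == pytest.approx(100.0)

    def test_single_point_in_window_is_zero(self):
        c = Chromatogram(500.0, 10.0, np.array([0.0, 1.0, 2.0]), np.array([1.0, 5.0, 1.0]))
        assert integrate_area(c, (0.9, 1.1)) == 0.0

    def test_matches_quadrature_oracle_on_random_traces(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 60))
            rt = np.sort(rng.uniform(0, 30, n))
            rt = np.unique(rt)
            inten = rng.uniform(0, 1e4, rt.size)
            c = Chromatogram(500.0, 10.0, rt, inten)
            lo, hi = sorted(rng.uniform(0, 30, 2))
            if lo == hi:
                continue
            assert integrate_area(c, (lo, hi)) == pytest.approx(
                trapezoid_oracle(rt, inten, lo, hi), abs=1e-9, rel=1e-9
            )

    def test_inverted_window_rejected(self):
        c = Chromatogram(500.0, 10.0, np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            integrate_area(c, (2.0, 1.0))


class TestApportionment:
    def test_three_to_one_split(self):
        out = apportion_isobaric(1000.0, ["x", "y"], {"x": 3.0, "y": 1.0})
        assert out == {"x": 750.0, "y": 250.0}

    def test_single_form_takes_all(self):
        assert apportion_isobaric(42.0, ["x"], {"x": 5.0}) == {"x": 42.0}

    def test_equal_intensities_split_equally(self):
        out = apportion_isobaric(90.0, list("abc"), {k: 2.0 for k in "abc"})
        assert all(v == pytest.approx(30.0) for v in out.values())

    def test_outputs_sum_to_shared_area(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            forms = [f"f{i}" for i in range(n)]
            frag = {f: float(rng.uniform(0, 10)) for f in forms}
            if sum(frag.values()) == 0:
                continue
            shared = float(rng.uniform(0, 1e6))
            out = apportion_isobaric(shared, forms, frag)
            assert sum(out.values()) == pytest.approx(shared, rel=1e-12)

    def test_all_zero_intensities_flagged_and_split_equally(self, caplog):
        with caplog.at_level("WARNING"):
            out = apportion_isobaric(100.0, ["x", "y"], {"x": 0.0, "y": 0.0})
        assert "all-zero" in caplog.text
        assert out == {"x": 50.0, "y": 50.0}


class TestRelativeRatios:
    def test_simple_family_arithmetic(self):
        a = pd.DataFrame(
            {"s1": [300.0, 100.0, 600.0]},
            index=["H3:1-5:K2ac", "H3:1-5:K3ac", "H3:1-5:unmod"],
        )
        r = relative_ratios(a)
        assert r["s1"].tolist() == [0.3, 0.1, 0.6]

    def test_zero_area_form_keeps_partition(self):
        a = pd.DataFrame(
            {"s1": [0.0, 100.0, 300.0]},
            index=["H3:1-5:K2ac", "H3:1-5:K3ac", "H3:1-5:unmod"],
        )
        r = relative_ratios(a)
        assert r["s1"].tolist() == [0.0, 0.25, 0.75]

    def test_all_zero_family_is_undefined(self):
        a = pd.DataFrame(
            {"s1": [0.0, 0.0, 5.0]},
            index=["H3:1-5:K2ac", "H3:1-5:unmod", "H4:1-5:unmod"],
        )
        r = relative_ratios(a)
        assert r["s1"].isna().tolist() == [True, True, False]

    def test_missing_cells_treated_as_zero(self):
        a = pd.DataFrame(
            {"s1": [np.nan, 100.0]}, index=["H3:1-5:K2ac", "H3:1-5:unmod"]
        )
        r = relative_ratios(a)
        assert r["s1"].tolist() == [0.0, 1.0]

    def test_duplicate_keys_rejected(self):
        a = pd.DataFrame({"s1": [1.0, 2.0]}, index=["H3:1-5:unmod", "H3:1-5:unmod"])
        with pytest.raises(ValueError, match="duplicate"):
            relative_ratios(a)

    def test_ratio_conservation_on_random_tables(self, rng):
        for _ in range(50):
            a = random_area_table(rng, n_families=int(rng.integers(1, 5)))
            r = relative_ratios(a)
            fams = [":".join(k.split(":")[:2]) for k in r.index]
            sums = r.groupby(fams).sum().to_numpy()
            assert np.all(np.abs(sums - 1.0) <= 1e-9)
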