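"""codeml result parsing, LRT machinery and BEB site extraction."""

import math

import pytest

from selsites.fixtures import FixtureSpec, PlantedSite, write_codeml_fixture
from selsites.core import Method, Sign
from selsites.paml import (
    CodemlParseError,
    ModelFit,
    extract_beb_sites,
    likelihood_ratio_test,
    parse_codeml_result,
    tabulate_models,
)


@pytest.fixture
def spec():
    return FixtureSpec(
        seed=3,
        n_sites=250,
        n_sequences=12,
        planted_sites={
            110: PlantedSite(frozenset({Method.PAML_M8}), Sign.POSITIVE),
            42: PlantedSite(frozenset({Method.PAML_M8}), Sign.POSITIVE),
        },
    )


class TestParsing:
    def test_round_trip_recovers_planted_fit(self, spec, tmp_path):
        path = write_codeml_fixture(
            spec, "M8", tmp_path / "m8.txt",
            lnL=-2345.6789, np_=28, beb_sites=[(110, "R", 0.99)],
        )
        fit = parse_codeml_result(path, expected_model="M8")
        assert fit.model_id == "M8"
        assert fit.lnL == pytest.approx(-2345.6789, abs=1e-6)
        assert fit.np == 28
        assert [(s.site, s.residue, s.posterior) for s in fit.beb_sites] == [(110, "R", 0.99)]

    def test_null_model_has_no_beb(self, spec, tmp_path):
        fit = parse_codeml_result(write_codeml_fixture(spec, "M0", tmp_path / "m0.txt"))
        assert fit.beb_sites == []
        assert fit.params["w"] == pytest.approx(0.35)

    def test_m1a_m2a_np_difference_is_two(self, spec, tmp_path):
        null = parse_codeml_result(write_codeml_fixture(spec, "M1a", tmp_path / "m1a.txt"))
        alt = parse_codeml_result(write_codeml_fixture(spec, "M2a", tmp_path / "m2a.txt"))
        assert alt.np - null.np == 2

    def test_parameters_round_trip(self, spec, tmp_path):
        for model in ("M0", "M1a", "M2a", "M3", "M7", "M8"):
            fit = parse_codeml_result(
                write_codeml_fixture(spec, model, tmp_path / f"{model}.txt")
            )
            assert fit.model_id == model
            assert fit.params["kappa"] == pytest.approx(2.34567, abs=1e-5)
            assert fit.ntime == 2 * spec.n_sequences - 3

    def test_missing_lnl_line_is_parse_error(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("Model 8: beta&w>1\nnothing else\n")
        with pytest.raises(CodemlParseError, match="lnL"):
            parse_codeml_result(bad)

    def test_expected_model_mismatch_is_parse_error(self, spec, tmp_path):
        path = write_codeml_fixture(spec, "M7", tmp_path / "m7.txt")
        with pytest.raises(CodemlParseError, match="expected model M8"):
            parse_codeml_result(path, expected_model="M8")

    def test_malformed_beb_row_reports_line_number(self, spec, tmp_path):
        path = write_codeml_fixture(spec, "M8", tmp_path / "m8.txt",
                                    beb_sites=[(110, "R", 0.99)])
        text = path.read_text().replace("   110 R", "   xxx R")
        path.write_text(text)
        with pytest.raises(CodemlParseError, match=r"line \d+"):
            parse_codeml_result(path)

    def test_multi_model_file_splits_on_headers(self, spec, tmp_path):
        a = write_codeml_fixture(spec, "M7", tmp_path / "a.txt").read_text()
        b = write_codeml_fixture(spec, "M8", tmp_path / "b.txt").read_text()
        combined = tmp_path / "batch.txt"
        combined.write_text(a + "\n" + b)
        fits = parse_codeml_result(combined)
        assert [f.model_id for f in fits] == ["M7", "M8"]


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        null = ModelFit("M1a", lnL=-1000.0, np=26)
        alt = ModelFit("M2a", lnL=-1000.0, np=28)
        res = likelihood_ratio_test(null, alt)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_statistic_ten_df_two_closed_form(self):
        # 2*(lnL_alt - lnL_null) = 10 with df 2 -> p = exp(-5)
        null = ModelFit("M1a", lnL=-1005.0, np=26)
        alt = ModelFit("M2a", lnL=-1000.0, np=28)
        res = likelihood_ratio_test(null, alt, alpha=0.05)
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(math.exp(-5), rel=1e-12)
        assert res.significant

    def test_m0_m3_has_df_four(self, tmp_path):
        spec = FixtureSpec(seed=1, n_sites=100, n_sequences=10)
        null = parse_codeml_result(write_codeml_fixture(spec, "M0", tmp_path / "m0.txt"))
        alt = parse_codeml_result(write_codeml_fixture(spec, "M3", tmp_path / "m3.txt"))
        assert likelihood_ratio_test(null, alt).df == 4

    def test_m7_m8_has_df_two(self, tmp_path):
        spec = FixtureSpec(seed=1, n_sites=100, n_sequences=10)
        null = parse_codeml_result(write_codeml_fixture(spec, "M7", tmp_path / "m7.txt"))
        alt = parse_codeml_result(write_codeml_fixture(spec, "M8", tmp_path / "m8.txt"))
        assert likelihood_ratio_test(null, alt).df == 2

    def test_worse_alternative_is_clamped(self):
        null = ModelFit("M7", lnL=-1000.0, np=25)
        alt = ModelFit("M8", lnL=-1001.0, np=27)
        res = likelihood_ratio_test(null, alt)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_p_invariant_under_lnl_shift(self):
        null = ModelFit("M7", lnL=-1007.3, np=25)
        alt = ModelFit("M8", lnL=-1000.0, np=27)
        shifted = likelihood_ratio_test(
            ModelFit("M7", lnL=-7.3, np=25), ModelFit("M8", lnL=0.0, np=27)
        )
        assert likelihood_ratio_test(null, alt).p_value == pytest.approx(shifted.p_value)

    def test_unsupported_pairing_rejected(self):
        with pytest.raises(ValueError, match="unsupported LRT pairing"):
            likelihood_ratio_test(ModelFit("M0", lnL=-1.0, np=10),
                                  ModelFit("M8", lnL=-0.5, np=13))

    def test_corrupt_np_rejected(self):
        with pytest.raises(ValueError, match="np"):
            likelihood_ratio_test(ModelFit("M7", lnL=-1.0, np=27),
                                  ModelFit("M8", lnL=-0.5, np=27))


class TestBEBExtraction:
    def _fit(self, sites):
        from selsites.paml import BEBSite

        return ModelFit("M8", lnL=-1.0, np=10,
                        beb_sites=[BEBSite(s, r, pp) for s, r, pp in sites])

    def test_cutoff_filters_and_orders(self):
        fit = self._fit([(231, "K", 0.97), (110, "R", 0.99), (12, "A", 0.50)])
        calls = extract_beb_sites(fit, pp_cutoff=0.95)
        assert [c.site for c in calls] == [110, 231]
        assert all(c.sign.value == "positive" and c.significant for c in calls)

    def test_empty_beb_gives_empty_list(self):
        assert extract_beb_sites(self._fit([]), 0.95) == []

    def test_monotone_in_cutoff(self):
        fit = self._fit([(10, "A", 0.96), (20, "C", 0.991), (30, "D", 0.955)])
        loose = {c.site for c in extract_beb_sites(fit, 0.95)}
        tight = {c.site for c in extract_beb_sites(fit, 0.99)}
        assert tight <= loose

    def test_null_model_rejected(self):
        with pytest.raises(ValueError, match="alternative model"):
            extract_beb_sites(ModelFit("M7", lnL=-1.0, np=10), 0.95)


class TestTabulation:
    def test_tables_match_source_fits(self, spec, tmp_path):
        fits = [
            parse_codeml_result(write_codeml_fixture(spec, m, tmp_path / f"{m}.txt"))
            for m in ("M0", "M3")
        ]
        omega, lnl = tabulate_models(fits)
        assert list(lnl["model"]) == ["M0", "M3"]
        assert list(lnl["np"]) == [f.np for f in fits]
        assert list(lnl["lnL"]) == pytest.approx([f.lnL for f in fits])
        assert omega.loc[0, "w"] == pytest.approx(fits[0].params["w"])

    def test_empty_input_gives_headers_only(self):
        omega, lnl = tabulate_models([])
        assert len(omega) == 0 and len(lnl) == 0
        assert list(lnl.columns) == ["model", "np", "lnL"]

    def test_duplicate_model_rejected(self):
        fit = ModelFit("M0", lnL=-1.0, np=5)
        with pytest.raises(ValueError, match="duplicate"):
            tabulate_models([fit, fit])
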