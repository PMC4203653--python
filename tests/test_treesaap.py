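"""TreeSAAP property-result parsing and the PBS/PBR summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selsites.core import Method, Sign, ThresholdConfig, DEFAULT_REGISTRY
from selsites.fixtures import FixtureSpec, PlantedSite, write_treesaap_fixture
from selsites.treesaap import (
    EvpthwySeries,
    PropertyRecord,
    TreesaapParseError,
    build_pbr,
    build_pbs,
    export_window_plot_data,
    parse_evpthwy,
    parse_substs,
    pbs_statistics,
)

import numpy as np


@pytest.fixture
def spec():
    return FixtureSpec(
        seed=5,
        n_sites=200,
        n_sequences=10,
        planted_sites={
            7: PlantedSite(frozenset({Method.TREESAAP}), Sign.POSITIVE, n_properties=6),
            90: PlantedSite(frozenset({Method.TREESAAP}), Sign.POSITIVE, n_properties=1),
            120: PlantedSite(frozenset({Method.TREESAAP}), Sign.NEGATIVE, n_properties=2),
        },
    )


def _substs_file(tmp_path, prop="Hydrophobicity", rows=""):
    path = tmp_path / "p.substs.tsv"
    path.write_text(f"# property: {prop}\ncodon\tcategory\tz_score\tbranch\n{rows}")
    return path


class TestSubstsParsing:
    def test_round_trip(self, tmp_path):
        rows = "3\t8\t3.500\tbr1\n7\t7\t-4.100\tbr2\n9\t2\t1.000\t\n"
        records = parse_substs(_substs_file(tmp_path, rows=rows))
        assert len(records) == 3
        assert records[0] == PropertyRecord(3, "Hydrophobicity", 8, 3.5, "br1")
        assert records[2].branch is None

    def test_empty_rows_section(self, tmp_path):
        assert parse_substs(_substs_file(tmp_path)) == []

    def test_case_variant_property_resolves(self, tmp_path):
        records = parse_substs(_substs_file(tmp_path, prop="polarity", rows="1\t7\t3.2\t\n"))
        assert records[0].property == "Polarity"

    def test_unknown_property_errors_with_hint(self, tmp_path):
        with pytest.raises(TreesaapParseError, match="did you mean"):
            parse_substs(_substs_file(tmp_path, prop="Polaritee", rows="1\t7\t3.2\t\n"))

    def test_category_out_of_range_rejected(self, tmp_path):
        with pytest.raises(TreesaapParseError, match="category"):
            parse_substs(_substs_file(tmp_path, rows="1\t9\t3.2\t\n"))


class TestPBS:
    def test_single_qualifying_record(self, defaults):
        rows = build_pbs([PropertyRecord(7, "Polarity", 8, 3.5)], defaults)
        assert len(rows) == 1
        assert rows[0].codon == 7 and rows[0].total == 1
        assert rows[0].properties == ("Polarity (+)",)

    def test_z_below_boundary_excluded(self, defaults):
        assert build_pbs([PropertyRecord(7, "Polarity", 8, 3.0)], defaults) == []

    def test_z_at_boundary_included(self, defaults):
        assert build_pbs([PropertyRecord(7, "Polarity", 8, 3.09)], defaults)[0].total == 1

    def test_negative_z_counts_with_sign_annotation(self, defaults):
        rows = build_pbs([PropertyRecord(7, "Polarity", 7, -3.5)], defaults)
        assert rows[0].properties == ("Polarity (-)",)

    def test_category_outside_configured_set_excluded(self, defaults):
        assert build_pbs([PropertyRecord(7, "Polarity", 6, 5.0)], defaults) == []

    def test_distinct_property_count_brute_force(self, spec, tmp_path, defaults):
        root = write_treesaap_fixture(spec, tmp_path / "ts")
        records = parse_substs(root / "Substs")
        rows = build_pbs(records, defaults)
        # brute-force recount, independent of the grouping implementation
        expected = {}
        for r in records:
            ok = r.category in defaults.treesaap_categories and abs(r.z_score) >= defaults.treesaap_z
            if ok:
                expected.setdefault(r.codon, set()).add(r.property)
        assert {r.codon: r.total for r in rows} == {c: len(p) for c, p in expected.items()}
        assert {r.codon: r.total for r in rows} == {
            s: p.n_properties for s, p in spec.planted_sites.items()
        }

    def test_same_property_on_two_branches_counts_once(self, defaults):
        rows = build_pbs(
            [PropertyRecord(7, "Polarity", 8, 3.5, "br1"),
             PropertyRecord(7, "Polarity", 8, 4.5, "br2")], defaults)
        assert rows[0].total == 1

    def test_invariant_to_record_order(self, spec, tmp_path, defaults):
        root = write_treesaap_fixture(spec, tmp_path / "ts")
        records = parse_substs(root / "Substs")
        assert build_pbs(records, defaults) == build_pbs(records[::-1], defaults)

    def test_raising_cutoff_never_increases_totals(self, spec, tmp_path, defaults):
        root = write_treesaap_fixture(spec, tmp_path / "ts")
        records = parse_substs(root / "Substs")
        loose = {r.codon: r.total for r in build_pbs(records, defaults)}
        tight = {r.codon: r.total for r in build_pbs(
            records, defaults.replace(treesaap_z=5.0))}
        for codon, total in tight.items():
            assert total <= loose[codon]


@st.composite
def pbs_fixture_records(draw):
    names = DEFAULT_REGISTRY.names
    n = draw(st.integers(1, 40))
    records = []
    for _ in range(n):
        records.append(PropertyRecord(
            codon=draw(st.integers(1, 30)),
            property=names[draw(st.integers(0, 30))],
            category=draw(st.integers(1, 8)),
            z_score=draw(st.floats(-8, 8, allow_nan=False)),
        ))
    return records


class TestPBSStatistics:
    def test_property_at_two_codons_counts_twice(self, defaults):
        rows = build_pbs(
            [PropertyRecord(3, "Polarity", 8, 3.5), PropertyRecord(7, "Polarity", 8, 3.5)],
            defaults)
        stats = pbs_statistics(rows)
        assert stats.loc[0, "property"] == "Polarity"
        assert stats.loc[0, "total"] == 2

    def test_empty_pbs_gives_empty_table(self):
        assert len(pbs_statistics([])) == 0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(records=pbs_fixture_records())
    def test_counts_conserve_pbs_totals(self, records):
        rows = build_pbs(records, ThresholdConfig())
        stats = pbs_statistics(rows)
        assert stats["total"].sum() == sum(r.total for r in rows)


class TestEvpthwy:
    def test_round_trip(self, spec, tmp_path):
        root = write_treesaap_fixture(spec, tmp_path / "ts")
        series = parse_evpthwy(root / "Evpthwy")
        assert series
        for s in series:
            assert s.z.shape == (len(s.windows), 8)
            starts = [w[0] for w in s.windows]
            assert starts == sorted(set(starts))

    def test_single_window_file(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text(
            "# property: Polarity\nfrom\tto\t"
            + "\t".join(f"z_cat{c}" for c in range(1, 9))
            + "\n1\t20\t0\t0\t0\t0\t0\t0\t3.5\t0\n"
        )
        series = parse_evpthwy(path)
        assert len(series) == 1 and series[0].windows == [(1, 20)]

    def test_missing_category_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# property: Polarity\nfrom\tto\tz1\n1\t20\t3.5\n")
        with pytest.raises(TreesaapParseError):
            parse_evpthwy(path)

    def test_non_monotonic_windows_rejected(self, tmp_path):
        z = "\t".join(["0.0"] * 8)
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# property: Polarity\nfrom\tto\t"
            + "\t".join(f"z_cat{c}" for c in range(1, 9))
            + f"\n21\t40\t{z}\n1\t20\t{z}\n"
        )
        with pytest.raises(TreesaapParseError, match="increasing"):
            parse_evpthwy(path)


def _series(prop, windows, z78):
    z = np.zeros((len(windows), 8))
    for i, (z7, z8) in enumerate(z78):
        z[i, 6], z[i, 7] = z7, z8
    return EvpthwySeries(property=prop, windows=windows, z=z)


class TestPBR:
    def test_single_passing_property(self, defaults):
        rows = build_pbr([_series("Polarity", [(1, 20)], [(0.0, 3.5)])], defaults)
        assert len(rows) == 1
        assert rows[0].total == 1 and rows[0].properties_positive == ("Polarity",)

    def test_boundary_z_included(self, defaults):
        rows = build_pbr([_series("Polarity", [(1, 20)], [(3.09, 0.0)])], defaults)
        assert rows and rows[0].properties_positive == ("Polarity",)

    def test_windows_without_qualifiers_omitted(self, defaults):
        rows = build_pbr(
            [_series("Polarity", [(1, 20), (11, 30)], [(0.0, 0.0), (0.0, 4.0)])], defaults)
        assert [(r.from_codon, r.to_codon) for r in rows] == [(11, 30)]

    def test_totals_match_brute_force_recount(self, spec, tmp_path, defaults):
        root = write_treesaap_fixture(spec, tmp_path / "ts")
        series = parse_evpthwy(root / "Evpthwy")
        rows = build_pbr(series, defaults)
        for row in rows:
            count = 0
            for s in series:
                for i, w in enumerate(s.windows):
                    if w != (row.from_codon, row.to_codon):
                        continue
                    zs = s.z[i, 6:8]
                    count += int((zs >= defaults.treesaap_z).any())
                    count += int((zs <= -defaults.treesaap_z).any())
            assert count == row.total
        assert all(r.total == len(r.properties_positive) + len(r.properties_negative)
                   for r in rows)


class TestPlotExport:
    def test_midpoints_and_round_trip(self, tmp_path):
        series = [_series("Polarity", [(1, 20), (11, 30)], [(0, 3.5), (0, 1.0)])]
        table = export_window_plot_data(series, "Polarity")
        assert list(table["midpoint"]) == [10.5, 20.5]
        tsv = tmp_path / "plot.tsv"
        table.to_csv(tsv, sep="\t", index=False)
        import pandas as pd

        back = pd.read_csv(tsv, sep="\t")
        assert back.equals(table)

    def test_unknown_property_errors(self):
        with pytest.raises(KeyError, match="no windowed series"):
            export_window_plot_data([_series("Polarity", [(1, 20)], [(0, 0)])], "Bulkiness")
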