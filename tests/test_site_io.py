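"""Site-table IO, validation, orientation, coverage filter, HPD intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from driftlik import site_io
from driftlik.site_io import (
    SiteTableError,
    combine_samples,
    coverage_filter,
    hpd_interval,
    orient_to_founder_minor,
    read_site_table,
    read_sync,
    to_records,
    write_site_table,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=site_io.SCHEMA)


@pytest.fixture
def three_rows():
    return make_table(
        [
            ("2L", 100, "A", "T", "p1", 0, "1", 30, 70, 500.0),
            ("2R", 200, "C", "G", "p1", 0, "1", 60, 40, 500.0),
            ("X", 300, "G", "A", "p1", 0, "1", 90, 10, 500.0),
        ]
    )


class TestReadWrite:
    def test_round_trip_identity(self, three_rows, tmp_path):
        path = tmp_path / "sites.tsv"
        write_site_table(three_rows, path)
        back = read_site_table(path)
        pd.testing.assert_frame_equal(back, three_rows)

    def test_three_row_fixture_gives_three_records(self, three_rows, tmp_path):
        path = tmp_path / "sites.tsv"
        write_site_table(three_rows, path)
        assert len(to_records(read_site_table(path))) == 3

    def test_negative_count_rejected_with_row_number(self, three_rows, tmp_path):
        bad = three_rows.copy()
        bad.loc[1, "ref_count"] = -5
        path = tmp_path / "bad.tsv"
        write_site_table(bad, path)
        with pytest.raises(SiteTableError, match="row 2"):
            read_site_table(path)
        with pytest.warns(UserWarning, match="row 2"):
            kept = read_site_table(path, strict=False)
        assert len(kept) == 2

    def test_unknown_chromosome_rejected(self, three_rows, tmp_path):
        bad = three_rows.copy()
        bad.loc[0, "chrom"] = "chrUn"
        path = tmp_path / "bad.tsv"
        write_site_table(bad, path)
        with pytest.raises(SiteTableError, match="unknown chromosome"):
            read_site_table(path)

    def test_missing_column_rejected(self, three_rows, tmp_path):
        path = tmp_path / "bad.tsv"
        write_site_table(three_rows.drop(columns=["alt_count"]), path)
        with pytest.raises(SiteTableError, match="alt_count"):
            read_site_table(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\t".join(site_io.SCHEMA) + "\n")
        with pytest.warns(UserWarning, match="empty"):
            df = read_site_table(path)
        assert df.empty

    def test_vcf_import(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")  # optional extra
        path = tmp_path / "sites.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Depths">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpopA\tpopB\n"
            "2L\t100\t.\tA\tT\t50\tPASS\t.\tGT:AD\t0/1:30,70\t0/1:55,45\n"
            "3R\t200\t.\tC\tG,A\t50\tPASS\t.\tGT:AD\t0/1:10,5,5\t0/1:9,4,4\n"
        )
        df = site_io.read_vcf(path, generation=75)
        # the multiallelic record is skipped; one biallelic site x 2 pools
        assert len(df) == 2
        row = df[df["population"] == "popA"].iloc[0]
        assert (row["ref_count"], row["alt_count"]) == (30, 70)
        assert row["generation"] == 75

    def test_sync_import(self, tmp_path):
        path = tmp_path / "counts.sync"
        path.write_text(
            "2L\t100\tA\t30:70:0:0:0:0\t50:50:0:0:0:0\n"
            "2R\t200\tC\t0:0:80:20:0:0\t0:0:90:10:0:0\n"
        )
        df = read_sync(path, populations=["p1", "p2"], generation=12)
        assert len(df) == 4
        row = df[(df["chrom"] == "2L") & (df["population"] == "p1")].iloc[0]
        assert (row["ref"], row["alt"]) == ("A", "T")
        assert (row["ref_count"], row["alt_count"]) == (30, 70)


class TestCoverageFilter:
    def test_bounds(self):
        rows = make_table(
            [
                ("2L", 1, "A", "T", "p", 0, "1", 5, 5, np.nan),  # cov 10 kept
                ("2L", 2, "A", "T", "p", 0, "1", 200, 26, np.nan),  # 226 removed
                ("2L", 3, "A", "T", "p", 0, "1", 4, 5, np.nan),  # 9 removed
                ("2L", 4, "A", "T", "p", 0, "1", 100, 125, np.nan),  # 225 kept
            ]
        )
        kept = coverage_filter(rows)
        assert list(kept["pos"]) == [1, 4]

    def test_idempotent(self, three_rows):
        once = coverage_filter(three_rows)
        twice = coverage_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestOrientation:
    def founder(self, alt_count, ref_count):
        return make_table(
            [("2L", 100, "A", "T", "SAIP", 0, "1", ref_count, alt_count, np.nan)]
        )

    def later(self, alt_count, ref_count):
        return make_table(
            [("2L", 100, "A", "T", "p1", 75, "1", ref_count, alt_count, np.nan)]
        )

    def test_minor_is_alt_when_rare_in_founder(self):
        out = orient_to_founder_minor(self.later(80, 20), self.founder(30, 70))
        assert out.loc[0, "minor_allele"] == "T"
        assert out.loc[0, "oriented_frequency"] == pytest.approx(0.8)

    def test_minor_is_ref_when_alt_common_in_founder(self):
        out = orient_to_founder_minor(self.later(80, 20), self.founder(70, 30))
        assert out.loc[0, "minor_allele"] == "A"
        assert out.loc[0, "oriented_frequency"] == pytest.approx(0.2)

    def test_tie_breaks_to_alt_and_is_flagged(self):
        out = orient_to_founder_minor(self.later(10, 90), self.founder(50, 50))
        assert out.loc[0, "minor_allele"] == "T"
        assert bool(out.loc[0, "founder_tie"])

    def test_reorienting_is_a_no_op(self):
        once = orient_to_founder_minor(self.later(80, 20), self.founder(30, 70))
        twice = orient_to_founder_minor(once, self.founder(30, 70))
        pd.testing.assert_frame_equal(once, twice)

    def test_site_missing_from_founder_raises(self):
        later = self.later(1, 1)
        later.loc[0, "pos"] = 999
        with pytest.raises(SiteTableError, match="absent from the founder"):
            orient_to_founder_minor(later, self.founder(30, 70))


class TestCombineSamples:
    def test_samples_are_summed(self):
        df = make_table(
            [
                ("2L", 100, "A", "T", "p1", 75, "1", 30, 70, 100.0),
                ("2L", 100, "A", "T", "p1", 75, "2", 40, 60, 300.0),
            ]
        )
        out = combine_samples(df)
        assert len(out) == 1
        assert out.loc[0, "ref_count"] == 70 and out.loc[0, "alt_count"] == 130
        assert out.loc[0, "maxqual"] == 300.0


def hpd_oracle(a, b, mass):
    """Density-threshold HPD: bisect the density cut level."""
    post = stats.beta(a, b)
    mode = (a - 1) / (a + b - 2)

    def interval(t):
        lo = (
            optimize.brentq(lambda x: post.pdf(x) - t, 1e-12, mode)
            if post.pdf(1e-12) < t
            else 0.0
        )
        hi = (
            optimize.brentq(lambda x: post.pdf(x) - t, mode, 1 - 1e-12)
            if post.pdf(1 - 1e-12) < t
            else 1.0
        )
        return lo, hi

    def excess(t):
        lo, hi = interval(t)
        return post.cdf(hi) - post.cdf(lo) - mass

    t = optimize.brentq(excess, 1e-9, post.pdf(mode) * (1 - 1e-9), xtol=1e-13)
    return interval(t)


class TestHpdInterval:
    def test_boundary_mode_starts_at_zero(self):
        lo, hi = hpd_interval(0, 100)
        assert lo == 0.0 and 0 < hi < 0.05

    def test_symmetric_about_half(self):
        lo, hi = hpd_interval(50, 100)
        assert lo + hi == pytest.approx(1.0, abs=1e-6)

    def test_matches_density_threshold_oracle(self):
        lo, hi = hpd_interval(5, 50, 0.95)
        olo, ohi = hpd_oracle(5.5, 45.5, 0.95)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)

    @pytest.mark.parametrize("succ,total", [(5, 50), (20, 40), (1, 10), (99, 100)])
    def test_mass_and_mode_containment(self, succ, total):
        lo, hi = hpd_interval(succ, total, 0.95)
        a, b = succ + 0.5, total - succ + 0.5
        post = stats.beta(a, b)
        assert post.cdf(hi) - post.cdf(lo) == pytest.approx(0.95, abs=1e-6)
        if a > 1 and b > 1:
            mode = (a - 1) / (a + b - 2)
            assert lo <= mode <= hi

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(0, 0)
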