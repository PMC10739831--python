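"""Welch tests, polynomial regression/selection, and disruption accounting."""

import math

import numpy as np
import pytest

from probeaudit.crossref import audit_cpgs, find_probe_snps
from probeaudit.errors import DataError, ValidationError
from probeaudit.manifest import InfiniumType, ProbeRecord, Strand, compute_probe_region
from probeaudit.meqtl_bias import (
    MeqtlRecord,
    build_report,
    classify_cpgs,
    compare_effect_sizes,
    disruption_impact,
    fit_polynomials,
    read_meqtl_table,
    select_degree,
    welch_test,
)
from probeaudit.variants import PopCounts, SNPRecord


def welch_oracle(a, b):
    """Closed-form Welch statistic, written independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def region_for(cpg, pos):
    return compute_probe_region(
        ProbeRecord(cpg_id=cpg, chrom="chr1", pos=pos, strand=Strand.F,
                    infinium_type=InfiniumType.II)
    )


def snp_at(pos, snp_id):
    return SNPRecord(chrom="chr1", pos=pos, snp_id=snp_id, ref="A", alt="G",
                     counts={"EUR": PopCounts(10, 10, 2)})


def build_audits(spec):
    """spec: list of (cpg_id, probe_pos, [(snp_id, snp_pos), ...])."""
    regions = [region_for(c, p) for c, p, _ in spec]
    snps = [snp_at(pos, sid) for _, _, hits in spec for sid, pos in hits]
    return audit_cpgs(regions, find_probe_snps(regions, snps))


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1, 2, 3], [1, 2, 3])
        assert res.mean_diff == 0
        assert res.p_value == pytest.approx(1.0)
        assert res.ci_low < 0 < res.ci_high

    def test_known_small_example(self):
        res = welch_test([1, 2, 3], [4, 5, 6])
        assert res.t_stat == pytest.approx(-3.674, abs=5e-4)
        assert res.p_value == pytest.approx(0.0214, abs=5e-4)
        assert res.df == pytest.approx(4.0)
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_translation_invariance(self):
        r1 = welch_test([1.0, 2.5, 3.1], [4.2, 5.0, 6.6, 7.0])
        r2 = welch_test([11.0, 12.5, 13.1], [14.2, 15.0, 16.6, 17.0])
        assert r1.t_stat == pytest.approx(r2.t_stat, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)
        assert (r1.ci_high - r1.ci_low) == pytest.approx(
            r2.ci_high - r2.ci_low, abs=1e-10)

    def test_degenerate_group_named_in_error(self):
        with pytest.raises(ValidationError, match="'b'"):
            welch_test([1, 2, 3], [5])
        with pytest.raises(ValidationError, match="zero variance"):
            welch_test([2, 2, 2], [1, 2, 3])

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.5, 2, rng.integers(3, 30))
            res = welch_test(a, b)
            t, df = welch_oracle(a, b)
            assert res.t_stat == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)


class TestClassifyCpgs:
    def test_fraction_among_meqtl_cpgs(self):
        audits = build_audits([
            ("cg1", 1000, [("rs1", 1000)]),
            ("cg2", 2000, [("rs2", 2010)]),
            ("cg3", 3000, []),
            ("cg4", 4000, []),
            ("cg5", 5000, [("rs3", 5005)]),
            ("cg6", 6000, []),
        ])
        f_meqtl, f_non = classify_cpgs(["cg1", "cg2", "cg3", "cg4"], audits)
        assert f_meqtl == 0.5
        assert f_non == 0.5  # cg5 has a SNP, cg6 does not

    def test_all_cpgs_meqtl_errors(self):
        audits = build_audits([("cg1", 1000, []), ("cg2", 2000, [])])
        with pytest.raises(DataError, match="complement"):
            classify_cpgs(["cg1", "cg2"], audits)

    def test_no_probe_snps_anywhere(self):
        audits = build_audits([("cg1", 1000, []), ("cg2", 2000, [])])
        assert classify_cpgs(["cg1"], audits) == (0.0, 0.0)

    def test_unknown_meqtl_cpg_errors(self):
        audits = build_audits([("cg1", 1000, [])])
        with pytest.raises(DataError, match="not audited"):
            classify_cpgs(["cg9"], audits)


class TestCompareEffectSizes:
    def test_magnitudes_compared(self):
        audits = build_audits([
            ("cg1", 1000, [("rs1", 1000)]), ("cg2", 2000, [("rs2", 2000)]),
            ("cg3", 3000, []), ("cg4", 4000, []),
        ])
        records = [MeqtlRecord("cg1", "m1", -2.0), MeqtlRecord("cg2", "m2", -2.0),
                   MeqtlRecord("cg3", "m3", 1.0), MeqtlRecord("cg4", "m4", 1.0)]
        with pytest.raises(ValidationError):
            # magnitudes within each group are constant -> zero variance
            compare_effect_sizes(records, audits)
        records[1] = MeqtlRecord("cg2", "m2", -2.5)
        records[3] = MeqtlRecord("cg4", "m4", 1.5)
        res, n_excluded = compare_effect_sizes(records, audits)
        assert n_excluded == 0
        assert res.mean_diff == pytest.approx(2.25 - 1.25)

    def test_delta_mode_excludes_incomplete_records(self):
        audits = build_audits([
            ("cg1", 1000, [("rs1", 1000)]), ("cg2", 2000, [("rs2", 2000)]),
            ("cg3", 3000, []), ("cg4", 4000, []),
        ])
        records = [
            MeqtlRecord("cg1", "m1", 1.0, 2.0, 0.5),
            MeqtlRecord("cg2", "m2", 1.0, 1.0, 0.2),
            MeqtlRecord("cg3", "m3", 1.0, 0.5, 0.1),
            MeqtlRecord("cg4", "m4", 1.0, 0.9, 0.2),
            MeqtlRecord("cg4", "m5", 1.0),  # no ancestry-specific effects
        ]
        res, n_excluded = compare_effect_sizes(records, audits, use="delta")
        assert n_excluded == 1
        assert res.n_a == 2 and res.n_b == 2

    def test_single_group_errors(self):
        audits = build_audits([("cg1", 1000, [("rs1", 1000)]),
                               ("cg2", 2000, [])])
        records = [MeqtlRecord("cg1", "m1", 1.0), MeqtlRecord("cg1", "m2", 2.0)]
        with pytest.raises(DataError, match="empty"):
            compare_effect_sizes(records, audits)


class TestFitPolynomials:
    def test_pure_cubic_is_interpolated(self):
        x = np.arange(11.0)
        fits = fit_polynomials(x, x**3, max_degree=3)
        assert fits[2].r2 == pytest.approx(1.0, abs=1e-12)
        assert fits[2].rss == pytest.approx(0.0, abs=1e-6)

    def test_constant_response_gives_zero_r2(self):
        fits = fit_polynomials(np.arange(10.0), np.full(10, 3.0), max_degree=2)
        assert all(f.r2 == 0.0 for f in fits)

    def test_exact_line_recovers_coefficients(self):
        x = np.arange(6.0)
        (fit,) = fit_polynomials(x, 2 + 3 * x, max_degree=1)
        assert fit.coefficients == pytest.approx((2.0, 3.0), abs=1e-10)

    def test_rss_monotone_r2_nondecreasing(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 50, 100)
        y = 1 + 0.1 * x + rng.normal(0, 1, 100)
        fits = fit_polynomials(x, y, max_degree=4)
        rss = [f.rss for f in fits]
        r2 = [f.r2 for f in fits]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))
        assert all(0 <= f.r2 <= 1 for f in fits)

    def test_degenerate_x_rejected(self):
        with pytest.raises(DataError, match="identical"):
            fit_polynomials(np.full(10, 2.0), np.arange(10.0), max_degree=2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="points"):
            fit_polynomials(np.arange(4.0), np.arange(4.0), max_degree=3)


class TestSelectDegree:
    def test_cubic_truth_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 50, 300)
        y = 2 - 0.2 * x + 0.007 * x**2 - 8e-5 * x**3 + rng.normal(0, 0.3, 300)
        fits = fit_polynomials(x, y, max_degree=3)
        sel = select_degree(fits)
        assert sel.chosen_degree == 3
        assert all(s.p_value < 0.05 for s in sel.steps)

    def test_perfect_fit_reports_infinite_f(self):
        from probeaudit.meqtl_bias import PolyFit

        fits = [
            PolyFit(degree=1, coefficients=(0.0, 1.0), rss=4.0, tss=10.0,
                    r2=0.6, n=20),
            PolyFit(degree=2, coefficients=(0.0, 1.0, 0.1), rss=0.0, tss=10.0,
                    r2=1.0, n=20),
        ]
        sel = select_degree(fits)
        assert sel.chosen_degree == 2
        assert math.isinf(sel.steps[-1].f_stat)
        assert sel.steps[-1].p_value == 0.0

    def test_numerically_perfect_cubic_still_chosen(self):
        x = np.arange(12.0)
        sel = select_degree(fit_polynomials(x, x**3, max_degree=3))
        assert sel.chosen_degree == 3
        assert sel.steps[-1].p_value < 1e-50

    def test_equal_rss_step_rejected(self):
        from probeaudit.meqtl_bias import PolyFit

        fits = [
            PolyFit(degree=1, coefficients=(0.0, 1.0), rss=4.0, tss=10.0,
                    r2=0.6, n=20),
            PolyFit(degree=2, coefficients=(0.0, 1.0, 0.0), rss=4.0, tss=10.0,
                    r2=0.6, n=20),
        ]
        sel = select_degree(fits)
        assert sel.steps[-1].f_stat == 0.0
        assert sel.steps[-1].p_value == pytest.approx(1.0)
        assert sel.chosen_degree == 1

    def test_linear_floor_when_nothing_significant(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 50, 200)
        y = rng.normal(0, 1, 200)  # no relationship at all
        sel = select_degree(fit_polynomials(x, y, max_degree=3))
        assert sel.chosen_degree >= 1
        assert len(sel.steps) == 3

    def test_requires_consecutive_degrees(self):
        x = np.arange(20.0)
        fits = fit_polynomials(x, x**2, max_degree=3)
        with pytest.raises(ValidationError, match="consecutive"):
            select_degree([fits[0], fits[2]])


class TestDisruptionImpact:
    def _setup(self):
        audits = build_audits([
            ("cg1", 1000, [("rs1", 1000)]),   # CpG-site SNP (index 0)
            ("cg2", 2000, [("rs2", 2005)]),   # body SNP (index 5)
            ("cg3", 3000, []),
            ("cg4", 4000, [("rs4", 4001)]),   # CpG-site SNP (index 1)
        ])
        records = [
            MeqtlRecord("cg1", "m1", 1.0), MeqtlRecord("cg1", "m2", 1.1),
            MeqtlRecord("cg2", "m3", 0.5), MeqtlRecord("cg3", "m4", 0.4),
            MeqtlRecord("cg4", "m5", 0.9),
        ]
        return audits, records

    def test_counting_example(self):
        audits, records = self._setup()
        fst = {"rs1": 0.2, "rs2": 0.9, "rs4": 0.05}
        imp = disruption_impact(records, audits, fst)
        # cg1 qualifies (index 0, theta 0.2); cg2's SNP is far from the CpG
        # despite theta 0.9; cg4's CpG-site SNP is below the Fst threshold
        assert imp.n_cpgs_total == 4
        assert imp.n_cpgs_disrupted_differentiated == 1
        assert imp.cpg_fraction == 0.25
        assert imp.n_assoc_impacted == 2
        assert imp.assoc_fraction == pytest.approx(0.4)
        assert imp.median_fst_implicated == pytest.approx(0.2)

    def test_threshold_inclusive(self):
        audits, records = self._setup()
        imp = disruption_impact(records, audits,
                                {"rs1": 0.1, "rs2": 0.0, "rs4": 0.099})
        assert imp.n_cpgs_disrupted_differentiated == 1

    def test_missing_fst_errors(self):
        audits, records = self._setup()
        with pytest.raises(DataError, match="rs4"):
            disruption_impact(records, audits, {"rs1": 0.2, "rs2": 0.2})

    def test_order_invariance_and_duplicates(self):
        audits, records = self._setup()
        fst = {"rs1": 0.2, "rs2": 0.9, "rs4": 0.05}
        base = disruption_impact(records, audits, fst)
        assert disruption_impact(list(reversed(records)),
                                 list(reversed(audits)), fst) == base


class TestReport:
    def test_missing_sections_are_null_and_flagged(self):
        report = build_report(provenance={"seed": 0})
        assert report["enrichment"] is None
        assert report["effect_size"]["beta"] is None
        assert report["complete"] is False

    def test_meqtl_table_round_trip(self, tmp_path):
        path = tmp_path / "meqtl.tsv"
        path.write_text(
            "cpg_id\tsnp_id\tbeta\tbeta_eur\tbeta_afr\n"
            "cg1\tm1\t0.5\t0.8\t0.2\n"
            "cg2\tm2\t-0.3\t\t\n"
        )
        recs = read_meqtl_table(path)
        assert recs[0].delta == pytest.approx(0.6)
        assert recs[1].delta is None

    def test_unbalanced_ancestry_betas_rejected(self):
        with pytest.raises(DataError, match="pairs"):
            MeqtlRecord("cg1", "m1", 1.0, beta_eur=0.5)
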