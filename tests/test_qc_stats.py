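"""QC statistics: CV, quartile report, dose-response/LOQ, correlation,
profiles.  Reference values come from direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidshot.lipid_model import SpeciesAnnotation
from lipidshot.qc_stats import (
    DoseResponse,
    ReplicateTable,
    class_profile,
    cv_percent,
    dose_response_fit,
    double_bond_profile,
    loq_estimate,
    pearson_log,
    quartile_cv_report,
)
from lipidshot.quantify import QuantifiedLipidome, SpeciesQuant


class TestCvPercent:
    def test_constant_is_zero(self):
        assert cv_percent([5, 5, 5]) == 0.0

    def test_hand_computed(self):
        assert cv_percent([90, 100, 110]) == pytest.approx(10.0)

    @given(st.lists(st.floats(1.0, 1e6), min_size=2, max_size=20),
           st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_formula(self, values, k):
        v = np.array(values)
        want = v.std(ddof=1) / v.mean() * 100
        assert cv_percent(v) == pytest.approx(want, rel=1e-10)
        assert cv_percent(k * v) == pytest.approx(cv_percent(v), rel=1e-9)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            cv_percent([1.0])


def make_table(n_species, n_reps=5, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    means = np.geomspace(0.05, 2500.0, n_species)
    data = means[:, None] * rng.lognormal(0.0, 0.1, (n_species, n_reps))
    df = pd.DataFrame(
        data,
        index=[f"SP {i:03d}" for i in range(n_species)],
        columns=[f"r{j}" for j in range(n_reps)],
    )
    g = pd.Series(groups, index=df.columns) if groups else None
    return ReplicateTable(df, g)


class TestQuartileReport:
    def test_224_species_split_56_each(self):
        report = quartile_cv_report(make_table(224))
        assert [r.n_species for r in report.rows] == [56, 56, 56, 56]

    def test_remainder_goes_to_abundant_quartiles(self):
        report = quartile_cv_report(make_table(10))
        assert [r.n_species for r in report.rows] == [3, 3, 2, 2]

    def test_equal_concentrations_split_by_name(self):
        df = pd.DataFrame(
            np.ones((8, 3)),
            index=[f"SP {c}" for c in "abcdefgh"],
            columns=list("xyz"),
        )
        report = quartile_cv_report(ReplicateTable(df))
        assert [r.n_species for r in report.rows] == [2, 2, 2, 2]

    def test_coverage_sums_to_100(self):
        report = quartile_cv_report(make_table(57))
        assert sum(r.coverage_mol_percent for r in report.rows) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_most_abundant_quartile_dominates_coverage(self):
        report = quartile_cv_report(make_table(224))
        assert report.rows[0].coverage_mol_percent > 80.0
        assert report.rows[3].coverage_mol_percent < 5.0

    def test_grouped_cv_sd(self):
        t = make_table(8, n_reps=6, groups=list("aaabbb"))
        report = quartile_cv_report(t)
        for row in report.rows:
            assert set(row.per_group_cv) == {"a", "b"}
            assert row.cv_sd_across_groups >= 0

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            quartile_cv_report(make_table(3))


class TestDoseResponse:
    def test_identity_line(self):
        d = DoseResponse([1, 10, 100], [[1.0], [10.0], [100.0]])
        slope, r2 = dose_response_fit(d)
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_proportional_response_absorbed_by_intercept(self):
        d = DoseResponse([1, 10, 100], [[2.0], [20.0], [200.0]])
        slope, r2 = dose_response_fit(d)
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        spiked = [1.0, 3.0, 10.0, 30.0, 100.0]
        measured = [[1.2], [2.9], [11.5], [27.0], [118.0]]
        x = np.log10(spiked)
        y = np.log10([m[0] for m in measured])
        n = len(x)
        sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
        slope_o = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        r_o = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx * sx) * (n * (y * y).sum() - sy * sy)
        )
        slope, r2 = dose_response_fit(DoseResponse(spiked, measured))
        assert slope == pytest.approx(slope_o, rel=1e-10)
        assert r2 == pytest.approx(r_o**2, rel=1e-10)


class TestLoq:
    def series(self, cvs, scale=1.0):
        spiked = [0.25, 1.0, 4.0, 16.0, 64.0]
        measured = []
        for c, cv in zip(spiked, cvs):
            sd = c * cv / 100.0
            measured.append([c * scale - sd, c * scale, c * scale + sd])
        return DoseResponse(spiked, measured)

    def test_clean_series_loq_is_lowest_level(self):
        d = self.series([5, 5, 5, 5, 5])
        assert loq_estimate(d) == 0.25

    def test_noisy_lowest_level_pushes_loq_up(self):
        d = self.series([35, 8, 8, 8, 8])
        assert loq_estimate(d) == 1.0

    def test_all_levels_noisy_is_above_range(self):
        d = self.series([30, 30, 30, 30, 30])
        assert loq_estimate(d) is None

    def test_monotone_in_cv_threshold(self):
        d = self.series([25, 18, 12, 6, 5])
        loqs = [loq_estimate(d, cv_threshold_percent=t) for t in (10, 15, 20, 30)]
        vals = [np.inf if q is None else q for q in loqs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestPearsonLog:
    def test_identity(self):
        a = {"PC 34:1": 10.0, "PC 36:2": 100.0, "SM 34:1;2": 1.0, "CE 18:1": 500.0}
        assert pearson_log(a, a) == pytest.approx(1.0)

    def test_global_scaling_invariant(self):
        a = {"PC 34:1": 10.0, "PC 36:2": 100.0, "SM 34:1;2": 1.0, "CE 18:1": 500.0}
        b = {k: 2 * v for k, v in a.items()}
        assert pearson_log(a, b) == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        a = {f"S{i}": v for i, v in enumerate([1.0, 5.0, 12.0, 80.0, 400.0])}
        b = {f"S{i}": v for i, v in enumerate([1.4, 3.9, 15.0, 60.0, 500.0])}
        xs = np.log10(list(a.values()))
        ys = np.log10(list(b.values()))
        want = np.corrcoef(xs, ys)[0, 1]
        assert pearson_log(a, b) == pytest.approx(want, rel=1e-10)

    def test_intersection_with_warning(self):
        a = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "only_a": 9.0}
        b = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "only_b": 9.0}
        with pytest.warns(UserWarning):
            r = pearson_log(a, b)
        assert r == pytest.approx(1.0)

    def test_too_few_shared(self):
        with pytest.raises(ValueError):
            pearson_log({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def lipidome(rows):
    return QuantifiedLipidome(
        species=[
            SpeciesQuant(SpeciesAnnotation(cls, c, db, oh), conc, cls)
            for cls, c, db, oh, conc in rows
        ]
    )


class TestProfiles:
    def test_single_class_is_100_percent(self):
        prof = class_profile(lipidome([("PC", 34, 1, 0, 10.0)]))
        assert prof["mol_percent"].tolist() == [100.0]

    def test_three_to_one_split(self):
        prof = class_profile(
            lipidome([("PC", 34, 1, 0, 75.0), ("SM", 34, 1, 2, 25.0)])
        )
        got = dict(zip(prof["class"], prof["mol_percent"]))
        assert got == {"PC": pytest.approx(75.0), "SM": pytest.approx(25.0)}

    def test_double_bond_profile(self):
        prof = double_bond_profile(
            lipidome([("PC", 34, 0, 0, 25.0), ("PC", 34, 1, 0, 75.0)])
        )
        got = dict(zip(prof["double_bonds"], prof["mol_percent"]))
        assert got == {0: pytest.approx(25.0), 1: pytest.approx(75.0)}

    def test_all_saturated(self):
        prof = double_bond_profile(
            lipidome([("PC", 34, 0, 0, 5.0), ("TAG", 51, 0, 0, 25.0)])
        )
        assert prof["mol_percent"].tolist() == [pytest.approx(100.0)]

    def test_per_class_normalization(self):
        prof = double_bond_profile(
            lipidome([("PC", 34, 0, 0, 10.0), ("PC", 34, 1, 0, 30.0),
                      ("SM", 34, 1, 2, 7.0)]),
            per_class=True,
        )
        pc = prof[prof["class"] == "PC"]
        assert pc["mol_percent"].sum() == pytest.approx(100.0)
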