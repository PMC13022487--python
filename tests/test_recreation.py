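import numpy as np
import pytest

from protoseg import (
    leave_one_out,
    recreate,
    select_population,
    signature_thresholds,
)
from protoseg.recreation import delta_or

from conftest import make_matrix, make_phenotypes


class TestSignatureThresholds:
    def test_percentile_boundaries(self, rng):
        m = make_matrix(rng.normal(size=(50, 1)))
        pooled = m.participant_ids[:20]
        vals = m.observed_values("P0", pooled)
        assert signature_thresholds(m, pooled, [("P0", "high")], 0)["P0"] == vals.min()
        assert signature_thresholds(m, pooled, [("P0", "high")], 100)["P0"] == vals.max()

    def test_linear_interpolation_convention(self):
        m = make_matrix(np.arange(1.0, 101.0)[:, None])
        thr = signature_thresholds(m, m.participant_ids, [("P0", "high")], 75)
        assert thr["P0"] == pytest.approx(75.25)

    def test_unobserved_protein_is_error(self):
        values = np.ones((10, 1))
        mask = np.zeros((10, 1), dtype=bool)
        mask[5:] = True
        m = make_matrix(values, mask)
        with pytest.raises(ValueError, match="P0"):
            signature_thresholds(m, m.participant_ids[:5], [("P0", "high")], 50)


class TestRecreate:
    def or_oracle(self, a, b, c, d):
        return (a * d) / (b * c)

    def test_or_matches_cross_product_formula(self):
        # selected/diseased 10, selected/healthy 490, unselected/diseased 10,
        # unselected/healthy 4490 -> OR = 9.163
        n = 5000
        values = np.zeros((n, 1))
        values[:500] = 1.0  # the 500 selected participants
        m = make_matrix(values)
        sick = set(m.participant_ids[:10]) | set(m.participant_ids[500:510])
        pheno = make_phenotypes(m.participant_ids, sick_of=sick)
        pooled = m.participant_ids[:500]
        curve = recreate(
            m, pheno, pooled, [("P0", "high")], "D50", percentile_grid=[0]
        )
        pt = curve.points[0]
        assert (pt.odds.a, pt.odds.b, pt.odds.c, pt.odds.d) == (10, 490, 10, 4490)
        assert pt.odds.value == pytest.approx(9.163, abs=1e-3)

    def test_null_disease_or_near_one(self, rng):
        n = 4000
        m = make_matrix(rng.normal(size=(n, 3)))
        sick = set(np.asarray(m.participant_ids)[rng.random(n) < 0.1])
        pheno = make_phenotypes(m.participant_ids, sick_of=sick)
        pooled = m.participant_ids[:1000]
        signature = [("P0", "high"), ("P1", "low")]
        curve = recreate(m, pheno, pooled, signature, "D50",
                         percentile_grid=[10, 30, 50, 70, 90])
        covered = sum(
            pt.odds.ci_low <= 1.0 <= pt.odds.ci_high
            for pt in curve.points
            if pt.odds.defined
        )
        assert covered >= 4  # 95% CIs should cover 1 nearly everywhere

    def test_percentile_zero_selects_everyone_observed(self, rng):
        m = make_matrix(rng.normal(size=(200, 1)))
        pheno = make_phenotypes(m.participant_ids, sick_of=set(m.participant_ids[:20]))
        curve = recreate(
            m, pheno, m.participant_ids, [("P0", "high")], "D50", percentile_grid=[0]
        )
        assert curve.points[0].selected_n == 200

    def test_missing_signature_value_is_unselected(self, rng):
        values = rng.normal(size=(100, 1))
        mask = np.ones((100, 1), dtype=bool)
        mask[:10] = False
        m = make_matrix(values, mask)
        thr = {"P0": -np.inf}
        sel = select_population(m, [("P0", "high")], thr)
        assert not sel[:10].any() and sel[10:].all()

    def test_empty_selection_flagged_undefined(self, rng):
        m = make_matrix(rng.normal(size=(100, 1)))
        pheno = make_phenotypes(m.participant_ids, sick_of=set(m.participant_ids[:5]))
        # threshold above the maximum: percentile 100 of pooled = global max
        pooled = m.participant_ids
        curve = recreate(m, pheno, pooled, [("P0", "high")], "D50",
                         percentile_grid=[100])
        pt = curve.points[0]
        # only the single maximum passes; with 1 selected the OR may be
        # defined, so force the empty case explicitly
        thr = {"P0": np.inf}
        sel = select_population(m, [("P0", "high")], thr)
        assert sel.sum() == 0

    def test_selection_count_table_matches_naive_oracle(self, rng):
        # the 2x2 cells equal a direct count over participants
        for _ in range(20):
            n = 500
            values = rng.normal(size=(n, 2))
            mask = rng.random((n, 2)) > 0.05
            m = make_matrix(values, mask)
            sick = set(np.asarray(m.participant_ids)[rng.random(n) < 0.2])
            pheno = make_phenotypes(m.participant_ids, sick_of=sick)
            pooled = list(np.asarray(m.participant_ids)[rng.random(n) < 0.3])
            if not pooled:
                continue
            sig = [("P0", "high"), ("P1", "low")]
            pct = float(rng.integers(5, 96))
            curve = recreate(m, pheno, pooled, sig, "D50", percentile_grid=[pct])
            pt = curve.points[0]
            thr = signature_thresholds(m, pooled, sig, pct)
            sel = set()
            for i, pid in enumerate(m.participant_ids):
                ok = (
                    m.mask[i, 0] and m.values[i, 0] >= thr["P0"]
                    and m.mask[i, 1] and m.values[i, 1] <= thr["P1"]
                )
                if ok:
                    sel.add(pid)
            a = len(sel & sick)
            b = len(sel - sick)
            c = len(sick - sel)
            d = n - a - b - c
            assert (pt.odds.a, pt.odds.b, pt.odds.c, pt.odds.d) == (a, b, c, d)
            if min(a, b, c, d) > 0:
                assert pt.odds.value == pytest.approx(self.or_oracle(a, b, c, d))


class TestLeaveOneOut:
    def test_selection_supersets_full_signature(self, rng):
        n = 800
        m = make_matrix(rng.normal(size=(n, 4)))
        pooled = m.participant_ids[:200]
        sig = [(f"P{j}", "high") for j in range(4)]
        for pct in (10, 50, 90):
            thr = signature_thresholds(m, pooled, sig, pct)
            full = select_population(m, sig, thr)
            for omit in range(4):
                reduced = [s for k, s in enumerate(sig) if k != omit]
                sub = select_population(m, reduced, thr)
                assert (full <= sub).all()

    def test_nonbinding_protein_leaves_curve_unchanged(self, rng):
        n = 500
        values = rng.normal(size=(n, 2))
        values[:, 1] = 100.0  # P1's threshold excludes nobody
        m = make_matrix(values)
        sick = set(np.asarray(m.participant_ids)[rng.random(n) < 0.1])
        pheno = make_phenotypes(m.participant_ids, sick_of=sick)
        pooled = m.participant_ids[:100]
        sig = [("P0", "high"), ("P1", "high")]
        full = recreate(m, pheno, pooled, sig, "D50")
        loo = leave_one_out(m, pheno, pooled, sig, "D50")
        deltas = delta_or(full, loo)
        assert np.allclose(deltas["P1"], 0.0, equal_nan=True)

    def test_planted_carrier_protein_has_largest_delta(self, rng):
        # only P0 is associated with disease; omitting it moves the OR most
        n = 4000
        values = rng.normal(size=(n, 3))
        risk = 1 / (1 + np.exp(-(-2.5 + 1.5 * values[:, 0])))
        sick = set(np.asarray([f"S{i}" for i in range(n)])[rng.random(n) < risk])
        m = make_matrix(values)
        pheno = make_phenotypes(m.participant_ids, sick_of=sick)
        pooled = [p for i, p in enumerate(m.participant_ids) if values[i, 0] > 1.0]
        sig = [(f"P{j}", "high") for j in range(3)]
        full = recreate(m, pheno, pooled, sig, "D50", percentile_grid=[50])
        loo = leave_one_out(m, pheno, pooled, sig, "D50", percentile_grid=[50])
        deltas = {p: abs(d[0]) for p, d in delta_or(full, loo).items()}
        assert max(deltas, key=deltas.get) == "P0"

    def test_requires_signature_of_two(self, rng):
        m = make_matrix(rng.normal(size=(50, 1)))
        pheno = make_phenotypes(m.participant_ids)
        with pytest.raises(ValueError):
            leave_one_out(m, pheno, m.participant_ids[:10], [("P0", "high")], "D50")
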