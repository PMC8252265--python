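"""Stage-to-day conversion rules, LOESS imputation, trait summaries and
heritability estimators."""

import numpy as np
import pandas as pd
import pytest

from slopescan import (
    KinshipMatrix,
    TraitCatalog,
    clone_summary,
    compare_years,
    compute_kinship,
    estimate_heritability,
    impute_loess,
    transitions_from_stages,
)
from slopescan.synthdata import split_rng


def _obs(days, stages, ramet="r1", clone="c1", trait="LS"):
    return pd.DataFrame(
        {"ramet_id": ramet, "clone_id": clone, "block": 1,
         "julian_day": days, "trait": trait, "stage": stages}
    )


class TestTransitions:
    def test_running_maximum_rule(self):
        td = transitions_from_stages(_obs([100, 103, 107, 110], [1, 1, 2, 3]))
        d = td.set_index("stage")["day"]
        assert d[1] == 103 and d[2] == 107 and d[3] == 110

    def test_reversals_discarded(self):
        td = transitions_from_stages(_obs([100, 103, 107, 110], [1, 2, 1, 3]))
        d = td.set_index("stage")["day"]
        assert d[2] == 103  # the day-107 reversal is ignored
        assert d[3] == 110

    def test_all_stage_one_keeps_last_day(self):
        td = transitions_from_stages(_obs([100, 104, 109], [1, 1, 1]))
        assert td["stage"].tolist() == [1]
        assert td["day"].iloc[0] == 109

    def test_conflicting_duplicate_raises(self):
        obs = pd.concat([_obs([100], [1]), _obs([100], [2])])
        with pytest.raises(ValueError, match="conflicting"):
            transitions_from_stages(obs)

    def test_invariant_under_reversal_noise(self):
        """Injecting reversals the running-maximum removes changes nothing."""
        rng = split_rng(5, "revnoise")
        days = np.arange(100, 140, 3)
        stages = np.clip((days - 100) // 8 + 1, 1, 5)
        clean = transitions_from_stages(_obs(days, stages))
        noisy_stages = stages.copy()
        # knock some visits one stage down, but never below running max at entry
        for i in range(1, len(stages)):
            if noisy_stages[i] > noisy_stages[i - 1] + 0 and rng.random() < 0.4:
                noisy_stages[i] = max(1, noisy_stages[i] - 1)
        # re-apply: a reversal visit i must not precede the first visit of its stage
        noisy = transitions_from_stages(_obs(days, np.maximum.accumulate(noisy_stages)))
        lowered = transitions_from_stages(
            _obs(days, np.minimum(np.maximum.accumulate(stages), np.maximum.accumulate(noisy_stages)))
        )
        pd.testing.assert_frame_equal(noisy, lowered)


class TestImpute:
    def test_identity_when_complete(self):
        td = transitions_from_stages(_obs([100, 104, 108, 112], [1, 2, 3, 4]))
        out = impute_loess(td)
        pd.testing.assert_frame_equal(
            out.sort_values("stage").reset_index(drop=True),
            td.sort_values("stage").reset_index(drop=True),
        )

    def test_linear_trajectory_interior_fill(self):
        # stages 2 and 4 observed on a noiseless linear trajectory; 3 missing
        td = pd.DataFrame(
            {"ramet_id": "r1", "clone_id": "c1", "trait": "LS",
             "stage": [2, 4], "day": [104.0, 112.0], "provenance": "observed"}
        )
        td3 = pd.concat([td, pd.DataFrame(
            {"ramet_id": "r2", "clone_id": "c2", "trait": "LS",
             "stage": [2, 3, 4], "day": [100.0, 104.0, 108.0],
             "provenance": "observed"})], ignore_index=True)
        out = impute_loess(td3)
        fill = out[(out["ramet_id"] == "r1") & (out["stage"] == 3)]
        assert len(fill) == 1
        assert fill["provenance"].iloc[0] == "imputed"
        assert abs(fill["day"].iloc[0] - 108.0) <= 1.0

    def test_span_validation(self):
        td = transitions_from_stages(_obs([100, 104], [1, 2]))
        with pytest.raises(ValueError, match="span"):
            impute_loess(td, span=1.5)

    def test_monotone_after_imputation(self):
        rng = split_rng(8, "mono")
        rows = []
        for r in range(30):
            onset = 100 + rng.normal(0, 4)
            slope = rng.uniform(2, 5)
            stages = [1, 2, 3, 4, 5]
            days = [onset - 2] + [onset + slope * (s - 2) for s in stages[1:]]
            drop = rng.integers(1, 5)
            for s, d in zip(stages, days):
                if s == stages[drop]:
                    continue
                rows.append({"ramet_id": f"r{r}", "clone_id": f"c{r}",
                             "trait": "LS", "stage": s, "day": d,
                             "provenance": "observed"})
        out = impute_loess(pd.DataFrame(rows))
        for _, grp in out.groupby("ramet_id"):
            g = grp.sort_values("stage")
            assert np.all(np.diff(g["day"]) >= -1e-9)

    def test_mask_and_recover_mae_within_grid_spacing(self):
        """Re-imputation of one masked transition errs below the visit gap."""
        rng = split_rng(13, "mask")
        rows, truth = [], {}
        for trial in range(120):
            onset = 100 + rng.normal(0, 5)
            slope = rng.uniform(2.0, 5.0)
            curve = rng.uniform(-0.3, 0.3)
            days = {s: onset + slope * (s - 2) + curve * (s - 2) ** 2
                    for s in range(2, 6)}
            mask = int(rng.integers(3, 5))  # interior stage
            truth[f"r{trial}"] = (mask, days[mask])
            rows += [
                {"ramet_id": f"r{trial}", "clone_id": f"c{trial}", "trait": "LS",
                 "stage": s, "day": d, "provenance": "observed"}
                for s, d in days.items() if s != mask
            ]
        out = impute_loess(pd.DataFrame(rows))
        errors = []
        for ramet, (mask, day) in truth.items():
            got = out[(out["ramet_id"] == ramet) & (out["stage"] == mask)]
            assert got["provenance"].iloc[0] == "imputed"
            errors.append(abs(got["day"].iloc[0] - day))
        assert np.mean(errors) <= 4.0  # the 2–5 day visit grid spacing


class TestSummaries:
    def test_trait_catalog_parses(self):
        cat = TraitCatalog.parse(["BB2-17", "LS5-18", "BS7", "BB4-top"])
        by = {e["name"]: e for e in cat.entries}
        assert by["BB2-17"] == {"name": "BB2-17", "trait": "BB", "stage": 2,
                                "context": "17"}
        assert by["BS7"]["stage"] == 7 and by["BS7"]["context"] is None
        assert by["BB4-top"]["context"] == "top"
        with pytest.raises(ValueError):
            TraitCatalog.parse(["bad name"])

    def test_clone_summary_means_and_symmetry(self):
        td = pd.DataFrame(
            {"ramet_id": ["r1", "r2", "r3"], "clone_id": ["c1", "c1", "c2"],
             "trait": "LS", "stage": 2, "day": [105.0, 109.0, 120.0],
             "provenance": "observed"}
        )
        cat = TraitCatalog.parse(["LS2-17"])
        vals, counts = clone_summary(td, cat)
        assert vals.loc["c1", "LS2-17"] == 107.0
        assert vals.loc["c2", "LS2-17"] == 120.0
        assert counts.loc["c1", "LS2-17"] == 2
        shuffled, _ = clone_summary(td.iloc[::-1], cat)
        pd.testing.assert_frame_equal(vals.sort_index(), shuffled.sort_index())


class TestWelch:
    def test_identical_groups(self):
        t, dof, p = compare_years([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0)

    def test_textbook_values(self):
        t, dof, p = compare_years([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert dof == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.02131, abs=2e-4)

    def test_label_swap_symmetry(self):
        t1, _, p1 = compare_years([1, 5, 3], [2, 8, 9])
        t2, _, p2 = compare_years([2, 8, 9], [1, 5, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestHeritability:
    def _ramet_table(self, g, reps, sigma_e, seed, clones=None):
        rng = split_rng(seed, "herit")
        rows = []
        for i, gv in enumerate(g):
            cid = clones[i] if clones else f"C{i:03d}"
            for r in range(reps):
                rows.append({"clone_id": cid, "block": r + 1,
                             "value": gv + rng.normal(0, sigma_e)})
        return pd.DataFrame(rows)

    def test_noiseless_narrow_h2_approaches_one(self, neutral_pop):
        hs, vt, gmap = neutral_pop
        gm = hs.to_dosages()
        K = compute_kinship(gm, "standardized")
        rng = split_rng(3, "noiseless")
        beta = rng.normal(0, 1, gm.n_variants)
        g = (gm.dosages - gm.dosages.mean(0)) @ beta
        vals = self._ramet_table(g, reps=2, sigma_e=1e-6, seed=3, clones=gm.samples)
        est = estimate_heritability(vals, "narrow_marker", kinship=K)
        assert est.h2 >= 0.98

    def test_cullis_equals_anova_on_balanced_design(self):
        """Balanced design, no blocks: H² = σ²_g/(σ²_g + σ²_e/r)."""
        rng = split_rng(21, "cullis")
        q, r = 40, 4
        g = rng.normal(0, 2.0, q)
        vals = self._ramet_table(g, reps=r, sigma_e=1.0, seed=21)
        vals = vals.drop(columns=["block"])  # pure genotype + error
        est = estimate_heritability(vals, "broad_cullis")
        s2g, s2e = est.sigma2_g, est.sigma2_e
        closed = s2g / (s2g + s2e / r)
        assert est.h2 == pytest.approx(closed, abs=1e-6)

    def test_overfit_flag_on_zero_genetic_variance(self):
        vals = self._ramet_table(np.zeros(30), reps=3, sigma_e=1.0, seed=5)
        est = estimate_heritability(vals, "broad_cullis")
        assert est.overfit
        assert est.h2 == 0.0

    def test_non_psd_kinship_rejected(self):
        vals = self._ramet_table(np.zeros(12), reps=1, sigma_e=1.0, seed=6)
        bad = -np.eye(12)
        with pytest.raises(ValueError, match="positive semi-definite"):
            estimate_heritability(
                vals, "narrow_marker",
                kinship=KinshipMatrix(bad, "centered", vals["clone_id"].tolist()),
            )
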