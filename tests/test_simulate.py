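"""Synthetic-data generator: determinism, distributional fidelity,
ground-truth consistency, and end-to-end recovery."""

import numpy as np
import pytest
from scipy.stats import binomtest

from whalepreg.bootstrap import BootstrapPregnancyModel
from whalepreg.hormones import process_assays
from whalepreg.morphometry import process_morph
from whalepreg.performance import evaluate
from whalepreg.simulate import SimulationConfig, simulate_dataset, truth_table


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_output(self):
        a = simulate_dataset(SimulationConfig(), rng=np.random.default_rng(3))
        b = simulate_dataset(SimulationConfig(), rng=np.random.default_rng(3))
        for x, y in ((a.assays, b.assays), (a.morph, b.morph),
                     (a.sightings, b.sightings), (a.truth, b.truth)):
            assert x.to_csv(index=False) == y.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = simulate_dataset(rng=np.random.default_rng(3))
        b = simulate_dataset(rng=np.random.default_rng(4))
        assert a.assays.to_csv() != b.assays.to_csv()


class TestTruth:
    def test_class_counts_match_config(self, sim_small):
        counts = sim_small.truth["class"].value_counts().to_dict()
        assert counts == sim_small.config.n_per_class

    def test_no_mf_pregnant_when_fraction_zero(self):
        ds = simulate_dataset(
            SimulationConfig(mf_pregnant_fraction=0.0), rng=np.random.default_rng(0)
        )
        t = truth_table(ds)
        assert not t.loc[t["class"] == "MF", "pregnant"].any()

    def test_all_pregnant_config(self):
        cfg = SimulationConfig(
            n_per_class={"PF": 30}, mf_pregnant_fraction=1.0
        )
        t = truth_table(simulate_dataset(cfg, rng=np.random.default_rng(1)))
        assert t["pregnant"].all()

    def test_mf_marginal_within_binomial_bounds(self):
        cfg = SimulationConfig(n_per_class={"MF": 200}, mf_pregnant_fraction=0.15)
        t = truth_table(simulate_dataset(cfg, rng=np.random.default_rng(5)))
        k = int(t["pregnant"].sum())
        ci = binomtest(k, 200).proportion_ci(0.999)
        assert ci.low <= 0.15 <= ci.high

    def test_pf_truth_consistent_with_calf_years(self, sim_small):
        t = truth_table(sim_small)
        s = sim_small.sightings.set_index("whale_id")
        for _, row in t[t["class"] == "PF"].iterrows():
            calf_years = {int(y) for y in str(s.loc[row["whale_id"], "calf_years"]).split(";") if y}
            assert row["pregnant"]
            assert row["year"] + 1 in calf_years

    def test_calf_loss_moves_pf_to_mf(self):
        cfg = SimulationConfig(n_per_class={"PF": 60}, calf_loss_rate=0.5)
        t = truth_table(simulate_dataset(cfg, rng=np.random.default_rng(2)))
        assert t["pregnant"].all()  # designated PF are all truly pregnant
        assert (t["class"] == "MF").sum() > 0  # some lost the calf sighting


class TestDistributionalFidelity:
    def test_class_conditional_moments_within_three_se(self):
        cfg = SimulationConfig(n_per_class={"PF": 300, "JF": 300})
        ds = simulate_dataset(cfg, rng=np.random.default_rng(9))
        t = ds.truth
        for cls, (mu, sd) in (("PF", cfg.w50_pregnant), ("JF", cfg.w50_nonpregnant)):
            vals = t.loc[t["class"] == cls, "w50_latent"]
            assert abs(vals.mean() - mu) < 3 * sd / np.sqrt(len(vals))
        for cls, (mu, sd) in (
            ("PF", cfg.fp4m_log_pregnant), ("JF", cfg.fp4m_log_nonpregnant)
        ):
            vals = t.loc[t["class"] == cls, "log_fp4m_latent"]
            assert abs(vals.mean() - mu) < 3 * sd / np.sqrt(len(vals))


class TestEndToEnd:
    def _annual_w50(self, ds):
        morph = process_morph(ds.morph)
        morph["record_id"] = morph["whale_id"] + ":" + morph["year"].astype(str)
        t = truth_table(ds).set_index("record_id")
        morph = morph.join(t[["class", "pregnant"]], on="record_id")
        return morph.dropna(subset=["class"])

    def test_zero_overlap_gives_perfect_w50_classification(self):
        cfg = SimulationConfig(
            n_per_class={"PF": 6, "JF": 24},
            w50_pregnant=(0.28, 0.002),
            w50_nonpregnant=(0.12, 0.002),
            w50_measurement_sd=0.001,
            p_early_season=0.0,
        )
        ds = simulate_dataset(cfg, rng=np.random.default_rng(21))
        annual = self._annual_w50(ds)
        est = BootstrapPregnancyModel(n_boot=60, random_state=2).fit(
            annual["w50_mean"].to_numpy(), forced=(annual["class"] == "PF").to_numpy()
        )
        pred = est.summaries_["point"].to_numpy() >= 0.75
        _, metrics = evaluate(pred, annual["pregnant"].to_numpy())
        assert metrics.accuracy == 100.0

    def test_w50_model_beats_hormone_model_under_study_conditions(self):
        """With study-like overlap, width-based classification outperforms
        the hormone-based one on known-status whale-years."""
        cfg = SimulationConfig(n_per_class={"PF": 12, "LF": 8, "JF": 30})
        ds = simulate_dataset(cfg, rng=np.random.default_rng(33))
        truth = truth_table(ds).set_index("record_id")

        annual_w = self._annual_w50(ds)
        est_w = BootstrapPregnancyModel(n_boot=150, random_state=4).fit(
            annual_w["w50_mean"].to_numpy(), forced=(annual_w["class"] == "PF").to_numpy()
        )
        _, m_w = evaluate(
            est_w.summaries_["point"].to_numpy() >= 0.75, annual_w["pregnant"].to_numpy()
        )

        horm = process_assays(ds.assays)
        horm["record_id"] = horm["whale_id"] + ":" + horm["year"].astype(str)
        horm = horm.join(truth[["class", "pregnant"]], on="record_id").dropna(subset=["class"])
        est_f = BootstrapPregnancyModel(n_boot=150, random_state=4).fit(
            horm["log_fp4m"].to_numpy(), forced=(horm["class"] == "PF").to_numpy()
        )
        _, m_f = evaluate(
            est_f.summaries_["point"].to_numpy() >= 0.75, horm["pregnant"].to_numpy()
        )
        assert m_w.accuracy > m_f.accuracy

    def test_em_recovers_generator_components(self):
        """EM on n=200 whale-years recovers the class-conditional means."""
        cfg = SimulationConfig(n_per_class={"PF": 100, "JF": 100})
        ds = simulate_dataset(cfg, rng=np.random.default_rng(8))
        from whalepreg.mixture import em_fit, label_components

        w50 = ds.truth["w50_latent"].to_numpy()
        fit = em_fit(w50, rng=0)
        labels = label_components(fit)
        # simulation-calibrated sampling sd of the ML component means
        se = 0.0027
        assert abs(fit.means[labels.high, 0] - cfg.w50_pregnant[0]) < 3 * se
        assert abs(fit.means[labels.low, 0] - cfg.w50_nonpregnant[0]) < 3 * se
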