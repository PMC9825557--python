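"""Median split, contrast machinery, convergence diagnostics, and a small
hierarchical fit."""

import numpy as np
import pandas as pd
import pytest

from amygaze import bayes
from amygaze._sampling import PosteriorDraws, SamplerConfig, diagnostics
from amygaze.bayes import (ShiftedLognormalModel, contrast, median_split,
                           summarize_contrast)


def cell_table(latencies_by_cell):
    rows = []
    for (instr, disr, hemi), lats in latencies_by_cell.items():
        for lat in lats:
            rows.append((0, instr, disr, hemi, "fear", lat))
    return pd.DataFrame(rows, columns=["participant", "instruction", "disruption",
                                       "hemifield_fear", "choice", "latency_ms"])


class TestMedianSplit:
    def test_even_cell_splits_in_half(self):
        table = cell_table({("Yield", "None", "L"): [200, 300, 400, 500]})
        out = median_split(table, cell_factors=("instruction", "disruption",
                                                "hemifield_fear"))
        early = set(out.loc[out["latency_class"] == "Early", "latency_ms"])
        assert early == {200, 300}

    def test_odd_cell_sends_median_to_late(self):
        table = cell_table({("Yield", "None", "L"): [200, 300, 400]})
        out = median_split(table, cell_factors=("instruction", "disruption",
                                                "hemifield_fear"))
        assert set(out.loc[out["latency_class"] == "Early", "latency_ms"]) == {200}
        assert out.loc[out["latency_ms"] == 300, "latency_class"].item() == "Late"

    def test_split_is_cellwise_not_global(self):
        table = cell_table({
            ("Yield", "None", "L"): [100, 120, 140, 160],
            ("Yield", "Ipsi", "L"): [500, 520, 540, 560],
        })
        out = median_split(table, cell_factors=("instruction", "disruption",
                                                "hemifield_fear"))
        # 160 is Late in its slow-free cell although globally fast
        assert out.loc[out["latency_ms"] == 160, "latency_class"].item() == "Late"
        assert out.loc[out["latency_ms"] == 500, "latency_class"].item() == "Early"

    def test_counts_differ_by_at_most_one_per_cell(self, latency_table):
        out = median_split(latency_table)
        for _, grp in out.groupby(["instruction", "disruption", "hemifield_fear"]):
            counts = grp["latency_class"].value_counts()
            assert abs(counts.get("Early", 0) - counts.get("Late", 0)) <= 1

    def test_cell_without_latencies_raises(self):
        table = cell_table({("Yield", "None", "L"): [200.0, 300.0]})
        table.loc[:, "latency_ms"] = np.nan
        with pytest.raises(ValueError):
            median_split(table, cell_factors=("instruction",))


class TestContrasts:
    def test_all_positive_draws_give_certain_effect(self):
        r = summarize_contrast(np.abs(np.random.default_rng(0).normal(1, 0.1, 4000)))
        assert r.p_effect == 1.0

    def test_symmetric_draws_give_half(self):
        x = np.concatenate([np.arange(1, 101), -np.arange(1, 101)])
        assert summarize_contrast(x).p_effect == 0.5

    def test_standard_normal_interval_matches_closed_form(self):
        x = np.random.default_rng(2).standard_normal(1_000_000)
        r = summarize_contrast(x)
        assert r.ci_low == pytest.approx(-1.96, abs=0.01)
        assert r.ci_high == pytest.approx(1.96, abs=0.01)

    def test_confound_reference_rejected(self):
        cd = pd.DataFrame({("Yield", "None", "L"): np.zeros(10)})
        with pytest.raises(ValueError, match="confound"):
            contrast(cd, {("Yield", "None", "L"): 1.0})

    def test_sum_coding_marginalises_to_zero(self):
        cols = bayes._sum_code(np.array(["L", "R", "L", "R"]), ("L", "R"))
        assert cols.sum() == 0.0

    def test_cell_matrix_reproduces_cell_means(self):
        X, cells, _ = bayes._cell_matrix([("instruction", ("Yield", "Oppose")),
                                          ("disruption", ("None", "Ipsi", "Contra"))])
        target = np.arange(len(cells), dtype=float)
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        np.testing.assert_allclose(X @ beta, target, atol=1e-10)


class TestDiagnostics:
    def make_draws(self, chains):
        return PosteriorDraws(draws=chains, names=["x"], rhat=np.array([1.0]),
                              ess=np.array([100.0]))

    def test_identical_distributions_pass(self, rng):
        chains = rng.standard_normal((4, 2000, 1))
        rep = diagnostics(self.make_draws(chains), ess_min=400)
        assert rep.rhat.max() < 1.01 and rep.passed

    def test_separated_chains_fail(self, rng):
        chains = rng.standard_normal((4, 500, 1)) * 0.01
        chains += np.arange(4)[:, None, None]
        rep = diagnostics(self.make_draws(chains))
        assert rep.rhat.max() > 1.5 and not rep.passed

    def test_ess_of_iid_draws_near_count(self, rng):
        chains = rng.standard_normal((4, 500, 1))
        rep = diagnostics(self.make_draws(chains))
        assert 0.8 * 2000 <= rep.ess_bulk.iloc[0] <= 1.25 * 2000

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            self.make_draws(rng.standard_normal((1, 100, 1)))


@pytest.fixture(scope="module")
def fitted(latency_table):
    cfg = SamplerConfig(n_walkers=48, n_burn=150, n_draws=150,
                        max_extensions=0, strict=False, seed=0)
    return ShiftedLognormalModel(sampler=cfg).fit(latency_table)


class TestSmallFit:

    def test_link_domains_respected(self, fitted):
        draws = fitted.draws_.to_frame()
        assert (np.exp(draws["log_sigma0"]) > 0).all()
        for nm in ("log_sd_mu", "log_sd_sigma", "log_sd_delta"):
            assert np.isfinite(draws[nm]).all()
        assert (fitted.cell_draws().to_numpy() > 0).all()

    def test_planned_contrasts_have_valid_intervals(self, fitted):
        for r in fitted.planned_contrasts().values():
            assert r.ci_low <= r.mean <= r.ci_high
            assert 0.0 <= r.p_effect <= 1.0
            assert r.scale == "ms"

    def test_random_intercepts_present_per_participant(self, fitted):
        names = fitted.draws_.names
        n_subj = fitted.table_["participant"].nunique()
        assert sum(n.startswith("eta_mu") for n in names) == n_subj

    def test_unknown_family_rejected(self, latency_table):
        with pytest.raises(ValueError, match="family"):
            bayes.fit_model(latency_table, "probit")

    def test_prior_predictive_latencies_plausible(self, rng):
        # draws from the latency model's priors should generate responses
        # overwhelmingly inside the physiological (0, 2000] ms range
        n = 5000
        mu = rng.normal(np.log(0.25), 1.0, n)
        sigma = np.exp(rng.normal(-1.0, 1.0, n))
        delta = 0.25 * 1.0 / (1.0 + np.exp(-rng.normal(0.0, 1.5, n)))
        lat_ms = 1000 * (delta + np.exp(rng.normal(mu, sigma)))
        assert np.mean((lat_ms > 0) & (lat_ms <= 2000)) > 0.85

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ShiftedLognormalModel().fit(pd.DataFrame(columns=[
                "participant", "instruction", "disruption", "hemifield_fear",
                "choice", "latency_ms"]))
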