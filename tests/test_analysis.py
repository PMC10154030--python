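"""Correlation summaries, size models and probability curves."""

import numpy as np
import pandas as pd
import pytest

from flockspread import InputError
from flockspread.analysis import (
    acquisition_profile,
    aggregate_correlations,
    assign_size_bins,
    fit_size_model,
    order_metric_correlation,
    social_prob_curve,
)
from flockspread.contagion import (
    DiffusionRun,
    RuleSpec,
    replicate_diffusions,
    run_diffusion,
)
from flockspread.metrics import node_metrics
from conftest import complete_network, make_network


def fake_run(order, rule="simple", network_id="net", p_social=None, replicate=0):
    n = len(order)
    return DiffusionRun(
        network_id=network_id,
        rule=RuleSpec(rule),
        demonstrator=order[0],
        acquisition_order=list(order),
        x=np.zeros(n),
        total_connections=np.zeros(n),
        T=np.zeros(n),
        p_social=np.zeros(n) if p_social is None else np.asarray(p_social),
        replicate=replicate,
    )


def metric_table(values, network_id="net"):
    """Table whose three standardized metrics all equal ``values``."""
    idx = [f"n{k}" for k in range(len(values))]
    df = pd.DataFrame(
        {
            "network_id": network_id,
            "weighted_clustering": values,
            "weighted_degree": values,
            "weighted_betweenness": values,
            "weighted_clustering_z": values,
            "weighted_degree_z": values,
            "weighted_betweenness_z": values,
        },
        index=pd.Index(idx, name="individual_id"),
    )
    return df


class TestOrderMetricCorrelation:
    def test_perfect_monotone(self):
        table = metric_table([0.0, 1.0, 2.0, 3.0])
        up = fake_run(["n0", "n1", "n2", "n3"])
        down = fake_run(["n0", "n3", "n2", "n1"])
        assert order_metric_correlation(up, table)["weighted_degree"] == 1.0
        assert order_metric_correlation(down, table)["weighted_degree"] == -1.0

    def test_hand_worked_rho(self):
        """Metric values (3, 1, 2) adopted in positions (1, 2, 3): rho = -0.5."""
        table = metric_table([10.0, 3.0, 1.0, 2.0])
        run = fake_run(["n0", "n1", "n2", "n3"])
        assert order_metric_correlation(run, table)["weighted_degree"] == pytest.approx(-0.5)

    def test_demonstrator_excluded(self):
        """The demonstrator's own metric must not affect rho."""
        lo = metric_table([-99.0, 1.0, 2.0, 3.0])
        hi = metric_table([+99.0, 1.0, 2.0, 3.0])
        run = fake_run(["n0", "n1", "n2", "n3"])
        assert order_metric_correlation(run, lo) == order_metric_correlation(run, hi)

    def test_constant_metric_flagged_nan(self):
        table = metric_table([5.0, 1.0, 1.0, 1.0])
        run = fake_run(["n0", "n1", "n2", "n3"])
        assert np.isnan(order_metric_correlation(run, table)["weighted_degree"])

    def test_mismatched_network_rejected(self):
        table = metric_table([0.0, 1.0, 2.0], network_id="other")
        with pytest.raises(InputError):
            order_metric_correlation(fake_run(["n0", "n1", "n2"]), table)


class TestAggregateCorrelations:
    def test_opposite_replicates_average_to_zero(self):
        table = metric_table([0.0, 1.0, 2.0, 3.0])
        runs = [
            fake_run(["n0", "n1", "n2", "n3"], replicate=0),
            fake_run(["n0", "n3", "n2", "n1"], replicate=1),
        ]
        rec = aggregate_correlations(runs, {"net": table})
        assert (rec["mean_rho"] == 0).all()
        assert (rec["n_replicates"] == 2).all()

    def test_single_replicate_passthrough(self):
        table = metric_table([10.0, 3.0, 1.0, 2.0])
        rec = aggregate_correlations([fake_run(["n0", "n1", "n2", "n3"])],
                                     {"net": table})
        assert rec["mean_rho"].unique() == pytest.approx([-0.5])

    def test_undefined_replicates_dropped_and_counted(self):
        table = metric_table([5.0, 1.0, 1.0, 1.0])
        rec = aggregate_correlations([fake_run(["n0", "n1", "n2", "n3"])],
                                     {"net": table})
        assert (rec["n_replicates"] == 0).all()
        assert (rec["n_dropped"] == 1).all()

    def test_fisher_option_changes_mean(self):
        table = metric_table([0.0, 1.0, 2.0, 3.0, 2.5])
        runs = [
            fake_run(["n0", "n1", "n2", "n3", "n4"], replicate=0),
            fake_run(["n0", "n2", "n1", "n3", "n4"], replicate=1),
        ]
        raw = aggregate_correlations(runs, {"net": table})
        fis = aggregate_correlations(runs, {"net": table}, fisher=True)
        assert not np.allclose(raw["mean_rho"], fis["mean_rho"])


def synthetic_records(rng, slope, n=300, loc_sd=0.05, week_sd=0.03, noise_sd=0.04):
    locs = [f"L{i}" for i in range(8)]
    u = dict(zip(locs, rng.normal(0, loc_sd, len(locs))))
    periods = [(2012 + y, w) for y in range(2) for w in range(1, 6)]
    v = {p: rng.normal(0, week_sd) for p in periods}
    rows = []
    for i in range(n):
        loc = locs[i % len(locs)]
        year, week = periods[i % len(periods)]
        size = int(rng.integers(10, 78))
        rows.append(
            {
                "network_id": f"net{i}",
                "location_id": loc,
                "year": year,
                "week": week,
                "network_size": size,
                "rule": "simple",
                "metric_name": "weighted_degree",
                "mean_rho": 0.1 + slope * size + u[loc] + v[(year, week)]
                + rng.normal(0, noise_sd),
                "n_replicates": 100,
                "n_dropped": 0,
            }
        )
    return pd.DataFrame(rows)


class TestFitSizeModel:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        df = synthetic_records(rng, slope=0.01, loc_sd=0, week_sd=0, noise_sd=0)
        res = fit_size_model(df, "simple", "weighted_degree")
        assert res.slope == pytest.approx(0.01, abs=1e-8)

    def test_recovers_negative_slope_with_noise(self):
        rng = np.random.default_rng(1)
        df = synthetic_records(rng, slope=-0.005)
        res = fit_size_model(df, "simple", "weighted_degree")
        assert res.ci_low <= -0.005 <= res.ci_high
        assert res.ci_low <= res.slope <= res.ci_high

    def test_constant_size_rejected(self):
        rng = np.random.default_rng(2)
        df = synthetic_records(rng, slope=0.0)
        df["network_size"] = 20
        with pytest.raises(InputError, match="constant"):
            fit_size_model(df, "simple", "weighted_degree")

    def test_single_location_flagged(self):
        rng = np.random.default_rng(3)
        df = synthetic_records(rng, slope=0.002)
        df["location_id"] = "L0"
        res = fit_size_model(df, "simple", "weighted_degree")
        assert res.flagged and "locations" in res.flag_reason


class TestCurvesAndProfiles:
    def test_size_bins_cover_all_networks(self):
        sizes = pd.Series({f"net{i}": s for i, s in enumerate([10, 12, 15, 22, 30, 44, 70])})
        bins = assign_size_bins(sizes, 4)
        assert bins.notna().all()
        assert bins.nunique() == 4

    def test_simple_rule_curve_rises_early(self, small_batch):
        nets, _ = small_batch
        net = nets[0]
        runs = replicate_diffusions(net, [RuleSpec("simple")], n_reps=200,
                                    master_seed=1)
        curve = social_prob_curve(runs, {net.network_id: net.size}, n_bins=1)
        curve = curve.sort_values("n_informed")
        early = curve["mean_p_social"].iloc[: net.size // 3].to_numpy()
        # rising trend; small Monte-Carlo wiggles allowed
        assert np.all(np.diff(early) > -0.02)
        assert early[-1] > early[0]

    def test_proportion_last_adopter_on_complete_network(self):
        """The final adopter on a complete uniform network has all its
        connections informed: p = s/(s+1) = 5/6 exactly."""
        net = complete_network(6, weight=0.4)
        run = run_diffusion(net, RuleSpec("proportion", s=5), "n0",
                            np.random.default_rng(0))
        assert run.p_social[-1] == pytest.approx(5 / 6)

    def test_profile_single_run_passthrough(self):
        table = metric_table([0.5, -0.5, 1.5, -1.5])
        run = fake_run(["n0", "n2", "n1", "n3"])
        prof = acquisition_profile([run], {"net": table}, n_bins=1)
        deg = prof[prof["metric_name"] == "weighted_degree"].sort_values("position")
        assert deg["mean_value"].tolist() == pytest.approx([0.5, 1.5, -0.5, -1.5])

    def test_empty_runs_rejected(self):
        with pytest.raises(InputError):
            social_prob_curve([], {}, 1)
        with pytest.raises(InputError):
            acquisition_profile([], {}, 1)
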