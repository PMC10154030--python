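"""Summaries of diffusion runs: metric-order correlations, size effects,
and social-learning-probability curves.

For every diffusion run the Spearman rank correlation is computed between
each individual's standardized network metric and the position at which it
adopted the behaviour, always excluding the demonstrator (its position is a
uniform draw, not an adoption).  Correlations are averaged over replicates
per network x rule x metric, and the dependence of that mean correlation on
network size is modelled with a linear mixed-effects model (random
intercepts for site identity and for week nested in year, mirroring the
repeated sampling design of weekend-scale networks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import InputError
from .metrics import NODE_METRICS

__all__ = [
    "order_metric_correlation",
    "aggregate_correlations",
    "SizeModelResult",
    "fit_size_model",
    "social_prob_curve",
    "acquisition_profile",
    "assign_size_bins",
]


def order_metric_correlation(run, metrics: pd.DataFrame) -> dict:
    """Spearman rho of acquisition position vs each standardized metric.

    Positions 2..N (the demonstrator is excluded).  Returns
    ``{metric_name: rho}`` with NaN where the metric is constant over the
    non-demonstrator individuals (rank correlation undefined).
    """
    if "network_id" in metrics.columns:
        net_ids = set(metrics["network_id"].unique())
        if net_ids != {run.network_id}:
            raise InputError(
                f"metrics table is for {sorted(net_ids)}, run is on {run.network_id}"
            )
    adopters = run.acquisition_order[1:]
    if len(adopters) < 2:
        raise InputError("order_metric_correlation: need N >= 3 individuals")
    positions = np.arange(2, len(adopters) + 2)
    out = {}
    for name in NODE_METRICS:
        values = metrics.loc[adopters, name + "_z"].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            out[name] = np.nan
        else:
            out[name] = stats.spearmanr(positions, values).statistic
    return out


def _mean_rho(values: pd.Series, fisher: bool) -> float:
    if not len(values):
        return np.nan
    if not fisher:
        return float(values.mean())
    z = np.arctanh(np.clip(values.to_numpy(), -1 + 1e-12, 1 - 1e-12))
    return float(np.tanh(z.mean()))


def aggregate_correlations(runs, metrics_by_network: dict,
                           network_info: dict | None = None,
                           fisher: bool = False) -> pd.DataFrame:
    """Average rho over replicates per network x rule x metric.

    ``metrics_by_network`` maps network_id to its node-metric table;
    ``network_info`` optionally maps network_id to a dict with
    ``location_id, year, week, network_size`` (filled from the metric table
    index length if absent).  Replicates with undefined rho are dropped and
    counted in ``n_dropped``.  The default is the arithmetic mean of raw
    rho values; ``fisher=True`` averages on the Fisher-z scale instead.
    """
    rows = []
    for run in runs:
        rhos = order_metric_correlation(run, metrics_by_network[run.network_id])
        for name, rho in rhos.items():
            rows.append((run.network_id, run.rule.rule, run.replicate, name, rho))
    per_run = pd.DataFrame(
        rows, columns=["network_id", "rule", "replicate", "metric_name", "rho"]
    )

    records = []
    for (nid, rule, metric), grp in per_run.groupby(
        ["network_id", "rule", "metric_name"], sort=True
    ):
        valid = grp["rho"].dropna()
        info = (network_info or {}).get(nid, {})
        records.append(
            {
                "network_id": nid,
                "location_id": info.get("location_id", np.nan),
                "year": info.get("year", np.nan),
                "week": info.get("week", np.nan),
                "network_size": info.get(
                    "network_size", len(metrics_by_network[nid])
                ),
                "rule": rule,
                "metric_name": metric,
                "mean_rho": _mean_rho(valid, fisher),
                "n_replicates": len(valid),
                "n_dropped": len(grp) - len(valid),
            }
        )
    return pd.DataFrame(records)


@dataclass
class SizeModelResult:
    """Mixed-model fit of mean correlation on network size."""

    rule: str
    metric_name: str
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float
    intercept: float
    vc_location: float
    vc_week_in_year: float
    resid_var: float
    n_obs: int
    converged: bool
    flagged: bool
    flag_reason: str = ""

    def summary(self) -> str:
        flag = f"  [FLAGGED: {self.flag_reason}]" if self.flagged else ""
        return (
            f"{self.rule}/{self.metric_name}: slope = {self.slope:.5f} "
            f"(SE {self.slope_se:.5f}, 95% CI [{self.ci_low:.5f}, "
            f"{self.ci_high:.5f}]), n = {self.n_obs}{flag}"
        )


def fit_size_model(records: pd.DataFrame, rule: str, metric_name: str) -> SizeModelResult:
    """LMM: mean_rho ~ network_size + (1 | location) + (1 | week-in-year).

    Random intercepts for site identity and for sampling week nested in
    year absorb repeated measures of the same site and weekend.  Singular or
    non-converged fits are flagged but still report the slope.
    """
    df = records[
        (records["rule"] == rule) & (records["metric_name"] == metric_name)
    ].dropna(subset=["mean_rho", "network_size"]).copy()
    if len(df) < 3:
        raise InputError(f"fit_size_model: too few records for {rule}/{metric_name}")
    if df["network_size"].nunique() < 2:
        raise InputError(
            f"fit_size_model: network_size is constant for {rule}/{metric_name}"
        )

    flagged, reasons = False, []
    if df["location_id"].nunique() < 2:
        flagged = True
        reasons.append("fewer than 2 locations")
    df["year_week"] = df["year"].astype(str) + ":" + df["week"].astype(str)
    if df["year_week"].nunique() < 2:
        flagged = True
        reasons.append("fewer than 2 sampling periods")

    model = sm.MixedLM.from_formula(
        "mean_rho ~ network_size",
        groups=np.ones(len(df)),
        vc_formula={
            "location": "0 + C(location_id)",
            "week_in_year": "0 + C(year_week)",
        },
        re_formula="0",
        data=df,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = model.fit(reml=True, method="lbfgs")
    singular = any("singular" in str(w.message).lower() or
                   "converge" in str(w.message).lower() for w in caught)
    if singular or not fit.converged:
        flagged = True
        reasons.append("singular or non-converged fit")

    slope = float(fit.fe_params["network_size"])
    se = float(fit.bse_fe["network_size"])
    ci = fit.conf_int().loc["network_size"]
    vcomp = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
    return SizeModelResult(
        rule=rule,
        metric_name=metric_name,
        slope=slope,
        slope_se=se,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        intercept=float(fit.fe_params["Intercept"]),
        vc_location=float(vcomp.get("location", np.nan)),
        vc_week_in_year=float(vcomp.get("week_in_year", np.nan)),
        resid_var=float(fit.scale),
        n_obs=len(df),
        converged=bool(fit.converged),
        flagged=flagged,
        flag_reason="; ".join(reasons),
    )


def assign_size_bins(sizes: pd.Series, n_bins: int = 4) -> pd.Series:
    """Quantile bins over network sizes, labelled by their size range."""
    unique = sizes.drop_duplicates()
    n_bins = max(1, min(n_bins, unique.nunique()))
    binned = pd.qcut(sizes, q=n_bins, duplicates="drop")
    return binned.apply(
        lambda iv: f"{int(np.ceil(iv.left))}-{int(iv.right)}"
        if isinstance(iv, pd.Interval) else str(iv)
    )


def _percentile_ci(values: np.ndarray) -> tuple:
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def social_prob_curve(runs, network_sizes: dict, n_bins: int = 4) -> pd.DataFrame:
    """Mean p_social (and 95% percentile CI) vs number already informed.

    The x-axis is the count of informed individuals at the moment of the
    adoption event (1 for the first post-demonstrator adoption).  Curves are
    reported per rule x network-size bin.
    """
    rows = []
    for run in runs:
        n = len(run.acquisition_order)
        for step in range(1, n):
            rows.append(
                (run.rule.rule, run.network_id, step, run.p_social[step])
            )
    if not rows:
        raise InputError("social_prob_curve: no runs provided")
    df = pd.DataFrame(rows, columns=["rule", "network_id", "n_informed", "p_social"])
    size_series = pd.Series(network_sizes)
    bin_by_net = assign_size_bins(size_series, n_bins)
    df["size_bin"] = df["network_id"].map(bin_by_net)

    out = []
    for (rule, size_bin, k), grp in df.groupby(
        ["rule", "size_bin", "n_informed"], sort=True, observed=True
    ):
        vals = grp["p_social"].to_numpy()
        lo, hi = _percentile_ci(vals)
        out.append(
            {
                "rule": rule,
                "size_bin": size_bin,
                "n_informed": k,
                "mean_p_social": vals.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "n_events": len(vals),
            }
        )
    return pd.DataFrame(out)


def acquisition_profile(runs, metrics_by_network: dict, n_bins: int = 4,
                        standardized_positions: bool = False) -> pd.DataFrame:
    """Mean standardized metric of the adopter at each acquisition position.

    With ``standardized_positions`` the position axis is rescaled to
    (pos - 1)/(N - 1) in ten deciles so networks of different size can be
    overlaid.
    """
    rows = []
    for run in runs:
        table = metrics_by_network[run.network_id]
        n = len(run.acquisition_order)
        z = table.loc[
            run.acquisition_order, [m + "_z" for m in NODE_METRICS]
        ].to_numpy(dtype=float)
        for step in range(n):
            if standardized_positions:
                pos = round(10 * step / (n - 1)) / 10 if n > 1 else 0.0
            else:
                pos = step + 1
            for j, metric in enumerate(NODE_METRICS):
                rows.append((run.rule.rule, run.network_id, metric, pos, z[step, j]))
    if not rows:
        raise InputError("acquisition_profile: no runs provided")
    df = pd.DataFrame(
        rows, columns=["rule", "network_id", "metric_name", "position", "value"]
    )
    sizes = {nid: len(metrics_by_network[nid]) for nid in df["network_id"].unique()}
    bin_by_net = assign_size_bins(pd.Series(sizes), n_bins)
    df["size_bin"] = df["network_id"].map(bin_by_net)

    out = []
    for (rule, metric, size_bin, pos), grp in df.groupby(
        ["rule", "metric_name", "size_bin", "position"], sort=True, observed=True
    ):
        vals = grp["value"].to_numpy()
        lo, hi = _percentile_ci(vals)
        out.append(
            {
                "rule": rule,
                "metric_name": metric,
                "size_bin": size_bin,
                "position": pos,
                "mean_value": vals.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "n": len(vals),
            }
        )
    return pd.DataFrame(out)
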