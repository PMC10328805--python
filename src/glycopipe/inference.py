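"""Per-drug paired tests, random-effects meta-analysis and evidence classes.

The within-patient lab changes from the case series are tested with a paired
(one-sample-on-differences) t-test per drug and site.  Site rows are pooled
with a DerSimonian-Laird (DL) random-effects model, both across the two sites
per drug and across all site x drug rows within a pharmacological class.
Published rows carry a mean and 95% CI rather than an SE, so the SE is
reconstructed from the CI width before pooling.

Evidence classification mirrors the dual-site replication logic: a drug shows
*both-site* evidence for a direction when the mean change has that sign and
p < alpha at the discovery and the replication site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairedTResult:
    n: int
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    zero_variance: bool = False


@dataclass
class MetaResult:
    """DerSimonian-Laird random-effects pool of k (estimate, se) pairs."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    tau2: float
    k: int


def paired_t(deltas: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test of within-patient changes against zero.

    ``t = mean / (sd / sqrt(n))`` with ``n - 1`` degrees of freedom; the 95%
    CI uses the same t quantile.  A zero-variance sample with nonzero mean is
    reported with p = 0 and ``zero_variance`` set.
    """
    x = np.asarray(deltas, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires at least 2 deltas")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        return PairedTResult(n, mean, 0.0, 0.0, mean, mean, float(t), p, True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTResult(
        n, mean, sd, float(se), mean - tcrit * se, mean + tcrit * se, float(t), p
    )


def se_from_ci(
    mean: float,
    ci_low: float,
    ci_high: float,
    n: int | None = None,
    quantile_rule: str = "t",
) -> float:
    """Reconstruct a standard error from a symmetric 95% CI.

    ``se = (ci_high - ci_low) / (2 q)`` with ``q`` the 97.5% t quantile at
    ``n - 1`` df (default; the site rows come from paired t-tests) or the
    normal 1.959964.  A degenerate zero-width CI returns 0.  A CI whose
    midpoint strays from the mean (the reconstruction assumes symmetry)
    triggers a warning.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    width = ci_high - ci_low
    if abs(0.5 * (ci_low + ci_high) - mean) > 0.05 * width + 1e-12:
        warnings.warn(
            f"CI midpoint {(ci_low + ci_high) / 2:.6g} is not centered on the "
            f"mean {mean:.6g}; reconstructed SE assumes a symmetric interval",
            stacklevel=2,
        )
    if quantile_rule == "t":
        if n is None or n < 2:
            raise ValueError("t quantile rule requires n >= 2")
        q = float(stats.t.ppf(0.975, n - 1))
    elif quantile_rule == "normal":
        q = float(stats.norm.ppf(0.975))
    else:
        raise ValueError("quantile_rule must be 't' or 'normal'")
    return (ci_high - ci_low) / (2.0 * q)


def dl_meta(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis.

    Fixed-effect weights ``w = se^-2`` give the heterogeneity statistic
    ``Q = sum w (theta - theta_FE)^2``; the moment estimate of the
    between-study variance is ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2
    / sum w))``.  Random-effects weights ``1/(se^2 + tau2)`` produce the
    pooled estimate; its CI and p use normal quantiles.
    """
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    k = theta.size
    if k == 0:
        raise ValueError("meta-analysis requires at least one input")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")

    if k == 1:
        pooled, pooled_se = float(theta[0]), float(se[0])
        q = tau2 = 0.0
    else:
        w = se**-2.0
        theta_fe = float(np.sum(w * theta) / np.sum(w))
        q = float(np.sum(w * (theta - theta_fe) ** 2))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w_re * theta) / np.sum(w_re))
        pooled_se = float(np.sum(w_re) ** -0.5)

    z = pooled / pooled_se
    zcrit = float(stats.norm.ppf(0.975))
    return MetaResult(
        pooled=pooled,
        se=pooled_se,
        ci_low=pooled - zcrit * pooled_se,
        ci_high=pooled + zcrit * pooled_se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        q=q,
        tau2=tau2,
        k=int(k),
    )


EVIDENCE_CATEGORIES = ("both_sites", "discovery_only", "replication_only", "neither")


def dual_site_evidence(
    results: pd.DataFrame,
    alpha: float = 0.05,
    direction: str = "increase",
) -> pd.Series:
    """Classify per-drug evidence across the two sites.

    ``results`` is a wide table with one row per drug:
    ``drug, mean_delta_discovery, p_discovery, mean_delta_replication,
    p_replication`` (the packaged site tables have this shape).  A site
    supports the drug when the mean change has the requested sign and
    p < alpha.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    sign = 1.0 if direction == "increase" else -1.0

    needed = [
        "mean_delta_discovery",
        "p_discovery",
        "mean_delta_replication",
        "p_replication",
    ]
    incomplete = results[needed].isna().any(axis=1)
    if incomplete.any():
        skipped = results.loc[incomplete, "drug"].tolist()
        warnings.warn(f"skipping drugs missing a site row: {skipped!r}", stacklevel=2)
        results = results[~incomplete]

    def hit(mean: pd.Series, p: pd.Series) -> pd.Series:
        return (np.sign(mean) == sign) & (p < alpha)

    disc = hit(results["mean_delta_discovery"], results["p_discovery"])
    rep = hit(results["mean_delta_replication"], results["p_replication"])
    cat = np.where(
        disc & rep,
        "both_sites",
        np.where(disc, "discovery_only", np.where(rep, "replication_only", "neither")),
    )
    return pd.Series(cat, index=results["drug"].to_numpy(), name="evidence")


def _long_rows(results: pd.DataFrame, quantile_rule: str) -> pd.DataFrame:
    """Wide site table -> long (drug, site, estimate, se) rows."""
    rows = []
    for _, r in results.iterrows():
        for site in ("discovery", "replication"):
            n = int(r[f"n_{site}"])
            se = se_from_ci(
                r[f"mean_delta_{site}"],
                r[f"ci_low_{site}"],
                r[f"ci_high_{site}"],
                n=n,
                quantile_rule=quantile_rule,
            )
            rows.append(
                {
                    "drug": r["drug"],
                    "site": site,
                    "estimate": r[f"mean_delta_{site}"],
                    "se": se,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def class_meta(
    results: pd.DataFrame,
    class_map: Mapping[str, str] | None = None,
    level: str = "drug",
    quantile_rule: str = "t",
) -> dict[str, MetaResult]:
    """Random-effects pool of site rows per drug or per drug class.

    At ``level='drug'`` each drug's two site rows are pooled; at
    ``level='class'`` all site x drug rows sharing a class (via
    ``class_map``) are pooled together.  SEs come from the printed CIs via
    :func:`se_from_ci`.
    """
    if level not in ("drug", "class"):
        raise ValueError("level must be 'drug' or 'class'")
    long = _long_rows(results, quantile_rule)
    if level == "class":
        if class_map is None:
            raise ValueError("class-level meta-analysis requires class_map")
        missing = set(long["drug"]) - set(class_map)
        if missing:
            raise KeyError(f"drugs missing from class map: {sorted(missing)!r}")
        long["unit"] = long["drug"].map(class_map)
    else:
        long["unit"] = long["drug"]
    out = {}
    for unit, grp in long.groupby("unit", sort=True):
        out[unit] = dl_meta(grp["estimate"].to_numpy(), grp["se"].to_numpy())
    return out


def forest_plot_frame(
    results: pd.DataFrame, quantile_rule: str = "t"
) -> pd.DataFrame:
    """Per-row forest-plot data (label, estimate, ci bounds, RE weight share)."""
    long = _long_rows(results, quantile_rule)
    zcrit = float(stats.norm.ppf(0.975))
    long["ci_low"] = long["estimate"] - zcrit * long["se"]
    long["ci_high"] = long["estimate"] + zcrit * long["se"]
    w = long["se"] ** -2.0
    long["weight"] = w / w.sum()
    long["label"] = long["drug"] + " (" + long["site"] + ")"
    return long[["label", "estimate", "ci_low", "ci_high", "weight"]]
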