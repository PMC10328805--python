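"""Two-sample Mendelian randomization with tissue-level expression instruments.

For a gene targeted by a drug, genetically predicted gene expression (GPGE)
associations with the drug's indication (exposure side) and with T2D
(outcome side) across tissues form the instrument set.  Only tissues where
the indication association is itself significant (p < 0.05) are used.

The inverse-variance-weighted (IVW) estimator combines the tissue pairs as

    beta_hat = sum_i b_trait,i * b_T2D,i / s_i^2  /  sum_i b_trait,i^2 / s_i^2
    se_hat   = ( sum_i b_trait,i^2 / s_i^2 )^(-1/2)

with ``s_i`` the T2D-side standard error -- algebraically the slope of the
no-intercept weighted regression of outcome betas on exposure betas.  Egger
regression frees the intercept to probe directional pleiotropy; multivariable
MR (MVMR) regresses the outcome betas jointly on several exposures' betas;
a negative-control outcome (one believed unaffected by any exposure, e.g.
natural hair color) probes residual population stratification.

Tissue-level instruments for one gene are correlated across tissues; the
estimator treats them as independent, which is reproduced here as standard
practice for this design and documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054


@dataclass
class MrEstimate:
    gene_id: str
    beta_mr: float
    se_mr: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_tissues: int
    method: str = "ivw"
    bias_flag: bool | None = None  # negative-control only


@dataclass
class EggerResult:
    gene_id: str
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float
    n_tissues: int


def tissue_filter(trait_assocs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep tissues whose indication-side GPGE association has p < alpha."""
    return trait_assocs[trait_assocs["p"] < alpha].reset_index(drop=True)


def summarize_trait_gpge(trait_assocs: pd.DataFrame):
    """Pooled indication-side GPGE effect across significant tissues.

    DerSimonian-Laird random effects over the tissue-level (beta, se); a
    single tissue passes through unchanged.
    """
    from .inference import dl_meta

    if trait_assocs.empty:
        raise ValueError("no tissues to summarize")
    return dl_meta(trait_assocs["beta"].to_numpy(), trait_assocs["se"].to_numpy())


def _match(trait: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    m = trait.merge(
        outcome, on=["gene_id", "tissue"], suffixes=("_trait", "_outcome")
    )
    if m.empty:
        raise ValueError("no common gene x tissue instruments")
    if (m["se_outcome"] <= 0).any():
        raise ValueError("outcome-side standard errors must be positive")
    return m


def beta_to_or(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, CI low, CI high, p) from a log-odds estimate and its SE."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(
        np.exp(beta + Z95 * se)
    ), p


def ivw_mr(trait: pd.DataFrame, outcome: pd.DataFrame, method: str = "ivw") -> MrEstimate:
    """Inverse-variance-weighted MR over matched gene x tissue instruments.

    ``trait`` should already be restricted to significant tissues
    (:func:`tissue_filter`); both tables need columns ``gene_id, tissue,
    beta, se``.
    """
    m = _match(trait, outcome)
    bt = m["beta_trait"].to_numpy(float)
    bo = m["beta_outcome"].to_numpy(float)
    w = m["se_outcome"].to_numpy(float) ** -2.0
    denom = float(np.sum(bt**2 * w))
    if denom == 0:
        raise ValueError("all exposure betas are zero; slope undefined")
    beta = float(np.sum(bt * bo * w) / denom)
    se = denom**-0.5
    or_, lo, hi, p = beta_to_or(beta, se)
    gene = ",".join(sorted(m["gene_id"].unique()))
    return MrEstimate(gene, beta, se, or_, lo, hi, p, int(len(m)), method)


def egger_mr(trait: pd.DataFrame, outcome: pd.DataFrame) -> EggerResult | None:
    """MR Egger: weighted regression of outcome betas with a free intercept.

    Returns ``None`` (not estimable) with fewer than 3 matched tissues.  The
    intercept's two-sided normal p probes directional pleiotropy.
    """
    m = _match(trait, outcome)
    if len(m) < 3:
        return None
    bt = m["beta_trait"].to_numpy(float)
    bo = m["beta_outcome"].to_numpy(float)
    w = m["se_outcome"].to_numpy(float) ** -2.0
    X = np.column_stack([np.ones_like(bt), bt])
    wx = X * w[:, None]
    xtwx = X.T @ wx
    coef = np.linalg.solve(xtwx, wx.T @ bo)
    cov = np.linalg.inv(xtwx)
    i_se, s_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    i_p = float(2.0 * stats.norm.sf(abs(coef[0] / i_se)))
    gene = ",".join(sorted(m["gene_id"].unique()))
    return EggerResult(gene, float(coef[0]), i_se, i_p, float(coef[1]), s_se, len(m))


def mvmr(outcome: pd.DataFrame, traits: dict[str, pd.DataFrame]) -> dict[str, MrEstimate]:
    """Multivariable MR: joint no-intercept weighted regression.

    ``traits`` maps exposure names to tissue-level GPGE tables; instruments
    are the gene x tissue rows present in *every* exposure table and the
    outcome table.  Raises on a rank-deficient exposure matrix, naming the
    collinear exposures.
    """
    if len(traits) < 2:
        raise ValueError("MVMR requires at least two exposures")
    names = list(traits)
    merged = outcome.rename(columns={"beta": "beta_outcome", "se": "se_outcome"})[
        ["gene_id", "tissue", "beta_outcome", "se_outcome"]
    ]
    for name in names:
        t = traits[name].rename(columns={"beta": f"beta_{name}"})[
            ["gene_id", "tissue", f"beta_{name}"]
        ]
        merged = merged.merge(t, on=["gene_id", "tissue"])
    if merged.empty:
        raise ValueError("no gene x tissue instruments shared by all exposures")

    B = merged[[f"beta_{n}" for n in names]].to_numpy(float)
    bo = merged["beta_outcome"].to_numpy(float)
    w = merged["se_outcome"].to_numpy(float) ** -2.0

    # an exposure with all-zero betas carries no information: drop it from
    # the design (its coefficient is unidentifiable) instead of failing
    informative = [j for j in range(len(names)) if np.any(B[:, j] != 0.0)]
    Bi = B[:, informative]
    wB = Bi * w[:, None]
    xtwx = Bi.T @ wB
    if np.linalg.matrix_rank(xtwx) < len(informative):
        collinear = [names[j] for j in informative]
        raise ValueError(f"collinear exposures in MVMR: {collinear!r}")
    coef = np.linalg.solve(xtwx, wB.T @ bo)
    cov = np.linalg.inv(xtwx)
    gene = ",".join(sorted(merged["gene_id"].unique()))
    out = {}
    for pos, j in enumerate(informative):
        se = float(np.sqrt(cov[pos, pos]))
        or_, lo, hi, p = beta_to_or(float(coef[pos]), se)
        out[names[j]] = MrEstimate(
            gene, float(coef[pos]), se, or_, lo, hi, p, int(len(merged)), "mvmr"
        )
    for j in range(len(names)):
        if j not in informative:
            out[names[j]] = MrEstimate(
                gene, 0.0, float("inf"), 1.0, 0.0, float("inf"), 1.0,
                int(len(merged)), "mvmr",
            )
    return out


def negative_control(
    trait: pd.DataFrame, control_outcome: pd.DataFrame, alpha: float = 0.05
) -> MrEstimate:
    """IVW MR against a negative-control outcome.

    A significant estimate (p < alpha) raises ``bias_flag``: the instruments
    associate with an outcome they should not affect, suggesting population
    stratification or other confounding of the GPGE associations.
    """
    est = ivw_mr(trait, control_outcome, method="negative_control")
    est.bias_flag = bool(est.p < alpha)
    return est
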