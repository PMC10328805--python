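"""TWAS-driven drug-repurposing candidate discovery.

Stage 1 of the pipeline: filter gene x tissue TWAS associations on
significance and colocalization evidence, join the surviving genes to a
drug-gene interaction catalog, and keep drug-gene pairs whose mechanism of
action is concordant with the direction of the genetically predicted gene
expression (GPGE) effect on disease risk.

The direction rule: a drug is a plausible repurposing candidate when its
pharmacological action pushes the target gene's activity in the direction
that genetics says lowers risk.  Concretely, if increased GPGE associates
with *decreased* T2D risk the drug must be an agonist/activator; if increased
GPGE associates with *increased* risk the drug must be an
antagonist/inhibitor/blocker.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .datasets import load_action_synonyms

#: Default TWAS significance threshold (Bonferroni-style, gene x tissue scale).
DEFAULT_P_THRESHOLD = 1.92e-7
#: Default colocalization posterior (PP.H4) threshold.
DEFAULT_COLOC_THRESHOLD = 0.8

ACTION_VOCABULARY = frozenset(
    {"agonist", "activator", "antagonist", "inhibitor", "blocker", "other"}
)
_ACTIVATING = frozenset({"agonist", "activator"})
_SUPPRESSING = frozenset({"antagonist", "inhibitor", "blocker"})


def normalize_action(action: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Map a free-text mechanism label onto the closed action vocabulary.

    Raises ``ValueError`` for labels absent from both the vocabulary and the
    synonym map.
    """
    a = action.strip().lower()
    if a in ACTION_VOCABULARY:
        return a
    synonyms = load_action_synonyms() if synonyms is None else synonyms
    if a in synonyms:
        return synonyms[a]
    raise ValueError(f"unknown mechanism-of-action label: {action!r}")


def select_significant_genes(
    twas: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    coloc_threshold: float = DEFAULT_COLOC_THRESHOLD,
) -> pd.DataFrame:
    """Filter a gene x tissue TWAS table to significant, colocalized genes.

    A gene is retained iff its minimum p-value across tissues is <=
    ``p_threshold`` and its maximum PP.H4 across tissues is >=
    ``coloc_threshold``.  The GPGE effect sign is taken from the minimum-p
    tissue; ties are broken by larger ``|beta|``, then by lexicographic
    tissue label, so the result is order-invariant.

    Parameters
    ----------
    twas
        Columns ``gene_id, tissue, beta, p, pp_h4``.

    Returns
    -------
    DataFrame with one row per kept gene: ``gene_id, gpge_sign, beta, p,
    pp_h4, tissue`` (the sign-defining tissue and its statistics).
    """
    if not (0 < p_threshold <= 1 and 0 < coloc_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    cols = ["gene_id", "gpge_sign", "beta", "p", "pp_h4", "tissue"]
    if twas.empty:
        return pd.DataFrame(columns=cols)

    per_gene = twas.groupby("gene_id").agg(min_p=("p", "min"), max_h4=("pp_h4", "max"))
    kept = per_gene[(per_gene["min_p"] <= p_threshold) & (per_gene["max_h4"] >= coloc_threshold)]
    if kept.empty:
        return pd.DataFrame(columns=cols)

    sub = twas[twas["gene_id"].isin(kept.index)].copy()
    sub["_absbeta"] = sub["beta"].abs()
    # deterministic representative row: min p, then max |beta|, then tissue
    sub = sub.sort_values(
        ["gene_id", "p", "_absbeta", "tissue"], ascending=[True, True, False, True]
    )
    rep = sub.groupby("gene_id", sort=True).head(1).drop(columns="_absbeta")
    rep["gpge_sign"] = rep["beta"].apply(lambda b: 1 if b >= 0 else -1)
    return rep[cols].reset_index(drop=True)


def direction_concordant(
    gpge_sign: int, action: str, synonyms: Mapping[str, str] | None = None
) -> bool:
    """Apply the direction-of-effect concordance rule to one drug-gene pair.

    ``gpge_sign`` is the sign of the disease-risk association per SD increase
    of predicted expression: +1 means more expression, more risk.
    """
    if gpge_sign not in (1, -1):
        raise ValueError("gpge_sign must be +1 or -1")
    a = normalize_action(action, synonyms)
    if gpge_sign == -1:
        return a in _ACTIVATING
    return a in _SUPPRESSING


def targeted_gene_percentage(n_target_genes: int, n_significant_genes: int) -> float | None:
    """Share of significant genes targeted by candidate drugs, one decimal.

    Reported truncated (not rounded) to one decimal place; ``None`` when the
    denominator is zero.
    """
    if n_significant_genes == 0:
        return None
    return math.floor(1000.0 * n_target_genes / n_significant_genes) / 10.0


def assemble_candidates(
    genes: pd.DataFrame,
    interactions: pd.DataFrame,
    diabetes_drugs: Iterable[str] = (),
    synonyms: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join significant genes to drug targets and screen on direction.

    Parameters
    ----------
    genes
        Output of :func:`select_significant_genes`.
    interactions
        Columns ``drug_id, gene_id, action, source_db``.  Duplicate drug-gene
        rows from multiple source databases collapse to one pair.
    diabetes_drugs
        Drugs already used in diabetes management; excluded from candidacy
        before any counting.

    Returns
    -------
    (pairs, summary)
        ``pairs`` holds every drug-gene pair whose gene survived stage 1,
        with a ``concordant`` flag (discordant pairs are retained for audit);
        diabetes drugs are dropped entirely.  ``summary`` holds ``n_drugs``
        (distinct drugs with at least one concordant pair),
        ``n_target_genes`` (genes covered by those concordant pairs),
        ``n_significant_genes`` and ``pct_significant_genes_targeted``.
    """
    if synonyms is None:
        synonyms = load_action_synonyms()
    diabetes = set(diabetes_drugs)
    n_signif = int(genes["gene_id"].nunique()) if not genes.empty else 0

    cols = ["drug_id", "gene_id", "gpge_sign", "action", "concordant"]
    if genes.empty or interactions.empty:
        pairs = pd.DataFrame(columns=cols)
    else:
        inter = interactions.copy()
        inter["action"] = inter["action"].map(lambda a: normalize_action(a, synonyms))
        # set semantics on (drug, gene): multiple source databases collapse
        inter = inter.sort_values(["drug_id", "gene_id", "action"]).drop_duplicates(
            ["drug_id", "gene_id", "action"]
        )
        pairs = inter.merge(genes[["gene_id", "gpge_sign"]], on="gene_id", how="inner")
        pairs = pairs[~pairs["drug_id"].isin(diabetes)]
        pairs["concordant"] = pd.array(
            [
                direction_concordant(s, a, synonyms)
                for s, a in zip(pairs["gpge_sign"], pairs["action"])
            ],
            dtype=bool,
        )
        pairs = pairs[cols].sort_values(["drug_id", "gene_id"]).reset_index(drop=True)

    conc = pairs[pairs["concordant"].astype(bool)]
    n_drugs = int(conc["drug_id"].nunique())
    n_target = int(conc["gene_id"].nunique())
    summary = {
        "n_drugs": n_drugs,
        "n_target_genes": n_target,
        "n_significant_genes": n_signif,
        "pct_significant_genes_targeted": targeted_gene_percentage(n_target, n_signif),
    }
    return pairs, summary
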