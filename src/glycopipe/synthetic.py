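"""Synthetic inputs with known ground truth for every pipeline stage.

Protected EHR extracts and GWAS summary statistics cannot ship with the
package, so this module generates structurally faithful stand-ins: a gene x
tissue TWAS table, a drug-gene interaction catalog, longitudinal EHR event
streams (prescriptions/mentions, outpatient and inpatient labs, pregnancy
flags, demographics) and tissue-level GPGE summary statistics for an
indication trait, for T2D and for a negative-control outcome.

Every injected quantity -- per-drug lab effects, the causal effect theta, the
pleiotropy intercept alpha, which drug-gene pairs are concordant -- is
recorded in :class:`SimTruth` so downstream stages can be tested for exact
recovery.  All randomness flows from explicit integer seeds; identical
arguments yield identical tables.

The generative model for labs is deliberately simple: patient baseline +
additive post-initiation drug effect + independent Gaussian measurement
noise, with lab times from a homogeneous Poisson process.  The drug effect
switches on after an onset lag (default 0 days for glucose, 30 days for
HbA1c, matching the follow-up window's 30-day blank).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ANALYTES = ("hba1c", "glucose")
GROUPS = ("experimental", "glucose_decreasing", "glucose_increasing")
_SOURCES = ("ChEMBL", "DGIdb", "NCI-DD")
_ACTIVATING = ("agonist", "activator")
_SUPPRESSING = ("antagonist", "inhibitor", "blocker")

#: TWAS discovery thresholds the generator designs around.
P_SIGNIFICANT = 1.92e-7
COLOC_SIGNIFICANT = 0.8


@dataclass
class SimTruth:
    """Ground truth injected by the generators.

    ``drug_effects`` maps drug id -> (delta HbA1c in %, delta glucose in
    mg/dL); ``theta`` is the causal T2D log-odds per unit of trait-side GPGE;
    ``alpha`` the directional-pleiotropy intercept; ``concordant_pairs`` the
    drug-gene pairs designed to survive discovery.
    """

    drug_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    theta: float = 0.0
    alpha: float = 0.0
    concordant_pairs: set[tuple[str, str]] = field(default_factory=set)
    seed: int = 0
    # bookkeeping beyond the headline fields
    significant_genes: set[str] = field(default_factory=set)
    gene_signs: dict[str, int] = field(default_factory=dict)
    diabetes_drugs: set[str] = field(default_factory=set)
    drug_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isfinite(self.theta) and np.isfinite(self.alpha)):
            raise ValueError("theta and alpha must be finite")


@dataclass
class EhrConfig:
    """Knobs of the synthetic EHR generator (times in integer days)."""

    n_patients: int
    study_span: int = 900
    lab_rate: float = 3.0  # expected labs per patient per 180 days, per analyte
    baseline_mean: dict = field(
        default_factory=lambda: {"hba1c": 7.0, "glucose": 140.0}
    )
    baseline_sd: dict = field(default_factory=lambda: {"hba1c": 0.8, "glucose": 25.0})
    noise_sd: dict = field(default_factory=lambda: {"hba1c": 0.3, "glucose": 20.0})
    onset_lag: dict = field(default_factory=lambda: {"hba1c": 30, "glucose": 0})
    contamination_fraction: float = 0.10
    pregnancy_rate: float = 0.02
    dialect: str = "fills"
    seed: int = 0
    persistent_fraction: float = 0.85
    missing_baseline_fraction: float = 0.05
    inpatient_fraction: float = 0.10
    qc_outlier_fraction: float = 0.01

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.study_span < 540:
            raise ValueError("study_span must allow 180-day windows around t0")
        if self.lab_rate < 0 or self.pregnancy_rate < 0:
            raise ValueError("rates must be >= 0")
        for d in (self.baseline_sd, self.noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")
        for frac in (
            self.contamination_fraction,
            self.persistent_fraction,
            self.missing_baseline_fraction,
            self.inpatient_fraction,
            self.qc_outlier_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dialect not in ("fills", "mentions"):
            raise ValueError("dialect must be 'fills' or 'mentions'")

    @classmethod
    def from_file(cls, path: str | Path) -> "EhrConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def generate_twas_catalog(
    n_genes: int, frac_significant: float, n_tissues: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, SimTruth]:
    """Gene x tissue TWAS table with a designed-in significant subset.

    Exactly ``round(frac_significant * n_genes)`` genes are built to pass the
    discovery filter (min p <= 1.92e-7 and max PP.H4 >= 0.8); the rest are
    built to fail at least one criterion (p, colocalization, or both).  The
    GPGE sign of each significant gene at its minimum-p tissue is recorded in
    the returned :class:`SimTruth`.
    """
    if n_genes < 1 or n_tissues < 1:
        raise ValueError("n_genes and n_tissues must be >= 1")
    if not 0.0 <= frac_significant <= 1.0:
        raise ValueError("frac_significant must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    tissues = [f"tissue_{j:02d}" for j in range(n_tissues)]
    n_sig = round(frac_significant * n_genes)
    sig_idx = set(rng.choice(n_genes, size=n_sig, replace=False).tolist())

    log10_thr = np.log10(P_SIGNIFICANT)
    rows = []
    truth = SimTruth(seed=seed)
    for i, g in enumerate(genes):
        betas = rng.normal(0.0, 1.0, n_tissues)
        if i in sig_idx:
            p = 10 ** rng.uniform(-6.0, 0.0, n_tissues)  # all above threshold
            h4 = rng.uniform(0.0, 1.0, n_tissues)
            j = int(rng.integers(n_tissues))
            p[j] = 10 ** rng.uniform(-12.0, log10_thr - 0.05)
            h4[j] = rng.uniform(COLOC_SIGNIFICANT, 1.0)
            truth.significant_genes.add(g)
            truth.gene_signs[g] = 1 if betas[j] >= 0 else -1
        else:
            mode = rng.choice(["p", "coloc", "both"])
            if mode in ("p", "both"):
                p = 10 ** rng.uniform(-6.0, 0.0, n_tissues)
            else:
                p = 10 ** rng.uniform(-12.0, 0.0, n_tissues)
            if mode in ("coloc", "both"):
                h4 = rng.uniform(0.0, COLOC_SIGNIFICANT - 0.01, n_tissues)
            else:
                # colocalized but (by mode) not significant
                h4 = rng.uniform(0.0, 1.0, n_tissues)
        for j in range(n_tissues):
            rows.append((g, tissues[j], betas[j], p[j], h4[j]))
    twas = pd.DataFrame(rows, columns=["gene_id", "tissue", "beta", "p", "pp_h4"])
    return twas, truth


def generate_drug_catalog(
    truth: SimTruth,
    n_drugs: int,
    concordant_fraction: float,
    seed: int = 0,
    diabetes_fraction: float = 0.1,
) -> tuple[pd.DataFrame, SimTruth]:
    """Drug-gene interaction catalog targeting the significant genes.

    ``round(concordant_fraction * n_drugs)`` drugs get a mechanism of action
    concordant with their target gene's GPGE sign; the rest violate the
    direction rule (or carry an uninformative action).  A
    ``diabetes_fraction`` of the concordant drugs is tagged in
    ``truth.diabetes_drugs`` to exercise the existing-indication exclusion;
    ``truth.concordant_pairs`` holds the designed surviving candidates.
    Some pairs are duplicated under a second source database to exercise set
    semantics downstream.
    """
    if not truth.significant_genes:
        raise ValueError("truth has no significant genes to target")
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValueError("concordant_fraction must lie in [0, 1]")
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    truth = copy.deepcopy(truth)  # callers keep their input unchanged
    rng = np.random.default_rng(seed)
    sig = sorted(truth.significant_genes)
    n_conc = round(concordant_fraction * n_drugs)
    conc_idx = set(rng.choice(n_drugs, size=n_conc, replace=False).tolist())

    rows = []
    for d in range(n_drugs):
        drug = f"DRUG{d:04d}"
        gene = sig[int(rng.integers(len(sig)))]
        sign = truth.gene_signs[gene]
        right = _SUPPRESSING if sign == 1 else _ACTIVATING
        wrong = (_ACTIVATING if sign == 1 else _SUPPRESSING) + ("other",)
        if d in conc_idx:
            action = right[int(rng.integers(len(right)))]
            is_diabetes = rng.random() < diabetes_fraction
            if is_diabetes:
                truth.diabetes_drugs.add(drug)
            else:
                truth.concordant_pairs.add((drug, gene))
        else:
            action = wrong[int(rng.integers(len(wrong)))]
        src = _SOURCES[int(rng.integers(len(_SOURCES)))]
        rows.append((drug, gene, action, src))
        if rng.random() < 0.2:  # duplicate under another database
            other = [s for s in _SOURCES if s != src]
            rows.append((drug, gene, action, other[int(rng.integers(2))]))
    cat = pd.DataFrame(rows, columns=["drug_id", "gene_id", "action", "source_db"])
    return cat, truth


def generate_ehr(config: EhrConfig, truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Longitudinal EHR tables under the additive post-initiation model.

    Each patient is assigned one series drug (round-robin over
    ``truth.drug_effects`` so every drug appears), an index day t0 at least
    180 days from either end of the study span, and Poisson-timed labs per
    analyte whose values are patient baseline + injected drug effect after
    the onset lag + Gaussian noise.  A ``contamination_fraction`` of patients
    additionally receives a drug from another group before, at, or after t0
    (uniformly), exercising each exclusion timing; a
    ``missing_baseline_fraction`` loses its pre-t0 labs entirely.

    Returns ``{"prescriptions", "labs", "pregnancy", "demographics"}``.
    """
    if not truth.drug_effects:
        raise ValueError("truth.drug_effects is empty")
    missing = set(truth.drug_effects) - set(truth.drug_groups)
    if missing:
        raise ValueError(f"drugs lack group assignment: {sorted(missing)!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    drugs = sorted(truth.drug_effects)
    by_group: dict[str, list[str]] = {}
    for d in drugs:
        by_group.setdefault(truth.drug_groups[d], []).append(d)

    pids = np.array([f"P{i:06d}" for i in range(n)])
    series_drug = np.array(drugs)[rng.permutation(np.arange(n) % len(drugs))]
    t0 = rng.integers(180, config.study_span - 180, size=n, endpoint=True)
    persistent = rng.random(n) < config.persistent_fraction
    contaminated = rng.random(n) < config.contamination_fraction
    no_baseline = rng.random(n) < config.missing_baseline_fraction

    # --- prescriptions -----------------------------------------------------
    rx_rows: list[tuple] = []
    is_fills = config.dialect == "fills"
    for i in range(n):
        d = series_drug[i]
        if is_fills:
            rx_rows.append((pids[i], d, int(t0[i]), "fill", 30))
            if persistent[i]:
                for k in (30, 60, 90):
                    rx_rows.append((pids[i], d, int(t0[i]) + k, "fill", 30))
        else:
            rx_rows.append((pids[i], d, int(t0[i]), "mention", np.nan))
            if persistent[i]:
                off = int(rng.integers(30, 150, endpoint=True))
                rx_rows.append((pids[i], d, int(t0[i]) + off, "mention", np.nan))
        if contaminated[i]:
            own = truth.drug_groups[d]
            pool = [x for g, ds in by_group.items() if g != own for x in ds]
            if pool:
                cdrug = pool[int(rng.integers(len(pool)))]
                timing = rng.choice(["before", "at_t0", "followup"])
                if timing == "before":
                    day = int(rng.integers(0, max(1, int(t0[i]))))
                elif timing == "at_t0":
                    day = int(t0[i])
                else:
                    day = int(t0[i]) + int(rng.integers(1, 180, endpoint=True))
                ev = ("fill", 30) if is_fills else ("mention", np.nan)
                rx_rows.append((pids[i], cdrug, day, *ev))
    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "drug_id", "day", "event_type", "days_supply"]
    )

    # --- labs --------------------------------------------------------------
    lab_frames = []
    deltas = {
        "hba1c": np.array([truth.drug_effects[d][0] for d in series_drug]),
        "glucose": np.array([truth.drug_effects[d][1] for d in series_drug]),
    }
    expected = config.lab_rate * config.study_span / 180.0
    for analyte in ANALYTES:
        base = rng.normal(config.baseline_mean[analyte], config.baseline_sd[analyte], n)
        counts = rng.poisson(expected, n)
        rep = np.repeat(np.arange(n), counts)
        days = rng.integers(0, config.study_span, size=rep.size, endpoint=True)
        keep = ~(no_baseline[rep] & (days < t0[rep]))
        rep, days = rep[keep], days[keep]
        onset = t0[rep] + config.onset_lag[analyte]
        values = (
            base[rep]
            + deltas[analyte][rep] * (days > onset)
            + rng.normal(0.0, config.noise_sd[analyte], rep.size)
        )
        outlier = rng.random(rep.size) < config.qc_outlier_fraction
        values = np.where(
            outlier, 2.0 if analyte == "hba1c" else 3000.0, values
        )
        setting = np.where(
            rng.random(rep.size) < config.inpatient_fraction, "inpatient", "outpatient"
        )
        lab_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids[rep],
                    "analyte": analyte,
                    "day": days,
                    "value": values,
                    "setting": setting,
                }
            )
        )
    labs = (
        pd.concat(lab_frames, ignore_index=True)
        .sort_values(["patient_id", "analyte", "day"], kind="stable")
        .reset_index(drop=True)
    )

    # --- pregnancy / demographics -----------------------------------------
    pregnant = rng.random(n) < config.pregnancy_rate
    pregnancy = pd.DataFrame(
        {
            "patient_id": pids[pregnant],
            "day": rng.integers(0, config.study_span, size=int(pregnant.sum()), endpoint=True),
        }
    )
    demographics = pd.DataFrame(
        {
            "patient_id": pids,
            "age": rng.integers(30, 80, size=n, endpoint=True),
            "sex": rng.choice(["F", "M"], size=n),
            "series_drug": series_drug,  # ground-truth assignment
        }
    )
    return {
        "prescriptions": prescriptions,
        "labs": labs,
        "pregnancy": pregnancy,
        "demographics": demographics,
    }


def generate_gpge_summary(
    n_tissues: int,
    theta: float,
    alpha: float = 0.0,
    beta_trait_params: tuple[float, float] = (0.5, 0.2),
    se_trait: float = 0.05,
    se_t2d: float = 0.05,
    seed: int = 0,
    gene_id: str = "GENE0000",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tissue-level GPGE summary statistics for MR.

    Trait-side betas are N(mu, sd) per ``beta_trait_params``; T2D-side betas
    follow ``beta_T2D = theta * beta_trait + alpha + N(0, se_t2d^2)``.  The
    negative-control outcome is generated under theta = 0, alpha = 0.

    Returns (trait table, T2D table, negative-control table), each with
    columns ``gene_id, tissue, beta, se, p``.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    if se_t2d <= 0 or se_trait <= 0:
        raise ValueError("standard errors must be positive")
    from scipy import stats

    rng = np.random.default_rng(seed)
    tissues = [f"tissue_{j:02d}" for j in range(n_tissues)]
    mu, sd = beta_trait_params
    b_trait = rng.normal(mu, sd, n_tissues)
    b_t2d = theta * b_trait + alpha + rng.normal(0.0, se_t2d, n_tissues)
    b_ctrl = rng.normal(0.0, se_t2d, n_tissues)

    def table(betas, se):
        p = 2.0 * stats.norm.sf(np.abs(betas / se))
        return pd.DataFrame(
            {
                "gene_id": gene_id,
                "tissue": tissues,
                "beta": betas,
                "se": se,
                "p": p,
            }
        )

    return table(b_trait, se_trait), table(b_t2d, se_t2d), table(b_ctrl, se_t2d)


def write_ehr_csvs(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write the EHR tables as headered CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {
        "prescriptions": "prescriptions.csv",
        "labs": "labs.csv",
        "pregnancy": "pregnancy.csv",
        "demographics": "demographics.csv",
    }
    paths = {}
    for key, fname in names.items():
        path = outdir / fname
        tables[key].to_csv(path, index=False)
        paths[key] = path
    return paths
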