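"""Germline x somatic interaction tests and case-control burden enrichment.

Pairwise co-occurrence / mutual exclusivity between germline carrier flags
and somatic functional-mutation flags is assessed with the two-sided Fisher
exact test on the 2x2 carrier table; gene-level case-control enrichment
against control-population carrier counts uses the same test.  P values are
adjusted across the tested family by Benjamini-Hochberg, and odds ratios are
displayed with the Haldane-Anscombe 0.5 correction when a cell is empty (the
exact test itself always runs on the raw counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairResult",
    "interaction_test",
    "pairwise_interactions",
    "bh_fdr",
    "covariate_adjusted_test",
    "case_control_enrichment",
    "subtype_stratified_enrichment",
    "signed_log_or_matrix",
]


@dataclass(frozen=True)
class PairResult:
    """One germline gene x somatic gene interaction test."""

    germline_gene: str
    somatic_gene: str
    table: tuple  # ((both, g_only), (s_only, neither))
    odds_ratio: float
    log10_or: float
    p: float
    fdr: float
    direction: str  # co_occurrence | mutual_exclusivity | none


def _display_or(a, b, c, d) -> tuple[float, float]:
    """OR and log10(OR), Haldane-Anscombe corrected if any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    return orr, float(np.log10(orr))


def interaction_test(cohort: pd.DataFrame, germline_gene: str, somatic_gene: str,
                     alpha: float = 0.05, fdr: float | None = None) -> PairResult:
    """Fisher exact test of one germline/somatic gene pair.

    ``cohort`` holds one row per patient with boolean columns
    ``g_<gene>`` (germline carrier) and ``s_<gene>`` (somatic functional
    mutation).  ``fdr`` is the BH-adjusted p when the pair is part of a
    family (see :func:`pairwise_interactions`); for a stand-alone test the
    raw p is used.  Direction is called at ``fdr < alpha`` by the side of
    the odds ratio; a constant column yields p = 1 and direction none.
    """
    g = cohort[f"g_{germline_gene}"].astype(bool).to_numpy()
    s = cohort[f"s_{somatic_gene}"].astype(bool).to_numpy()
    a = int((g & s).sum())
    b = int((g & ~s).sum())
    c = int((~g & s).sum())
    d = int((~g & ~s).sum())
    if g.all() or (~g).all() or s.all() or (~s).all():
        orr, l10 = _display_or(a, b, c, d)
        return PairResult(germline_gene, somatic_gene, ((a, b), (c, d)),
                          orr, l10, 1.0, 1.0, "none")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    orr, l10 = _display_or(a, b, c, d)
    q = p if fdr is None else fdr
    if q < alpha and orr > 1:
        direction = "co_occurrence"
    elif q < alpha and orr < 1:
        direction = "mutual_exclusivity"
    else:
        direction = "none"
    return PairResult(germline_gene, somatic_gene, ((a, b), (c, d)),
                      orr, l10, float(p), float(q), direction)


def pairwise_interactions(cohort: pd.DataFrame,
                          germline_genes: list[str],
                          somatic_genes: list[str],
                          alpha: float = 0.05) -> pd.DataFrame:
    """All germline x somatic pairs with family-wise BH correction."""
    raw = [interaction_test(cohort, g, s) for g in germline_genes for s in somatic_genes]
    qs = bh_fdr([r.p for r in raw])
    rows = []
    for r, q in zip(raw, qs):
        if q < alpha and r.odds_ratio > 1:
            direction = "co_occurrence"
        elif q < alpha and r.odds_ratio < 1:
            direction = "mutual_exclusivity"
        else:
            direction = "none"
        rows.append({"germline_gene": r.germline_gene, "somatic_gene": r.somatic_gene,
                     "n_both": r.table[0][0], "n_germline_only": r.table[0][1],
                     "n_somatic_only": r.table[1][0], "n_neither": r.table[1][1],
                     "odds_ratio": r.odds_ratio, "log10_or": r.log10_or,
                     "p": r.p, "fdr": q, "direction": direction})
    return pd.DataFrame(rows)


def covariate_adjusted_test(outcome, exposure, covariates: pd.DataFrame) -> dict:
    """Logistic frequency comparison adjusted for covariates (age, histology...).

    Fits outcome ~ exposure + covariates by maximum-likelihood logistic
    regression and reports the exposure's adjusted OR, Wald p and 95% CI.
    """
    import statsmodels.api as sm

    exog = pd.concat([pd.Series(np.asarray(exposure, float), name="exposure",
                                index=covariates.index), covariates], axis=1)
    exog = sm.add_constant(exog.astype(float), has_constant="add")
    fit = sm.Logit(np.asarray(outcome, float), exog).fit(disp=0)
    ci = fit.conf_int().loc["exposure"]
    return {"adjusted_or": float(np.exp(fit.params["exposure"])),
            "ci_lo": float(np.exp(ci[0])), "ci_hi": float(np.exp(ci[1])),
            "p": float(fit.pvalues["exposure"])}


def bh_fdr(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(v) for v in q]


def _enrich_one(gene, k1, n1, k2, n2):
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return {"gene": gene, "case_carriers": int(k1), "n_case": int(n1),
            "control_carriers": int(k2), "n_control": int(n2),
            "odds_ratio": float(orr), "ci_lo": float(lo), "ci_hi": float(hi),
            "p": float(p)}


def case_control_enrichment(case_counts: pd.Series | dict,
                            control_counts: pd.Series | dict,
                            n_case: int, n_control: int,
                            fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene carrier enrichment of cases over a control population.

    ``case_counts`` / ``control_counts`` map gene -> carrier count; genes
    absent from one side count zero carriers there.  Returns a table with
    OR, normal-approximation 95% CI on the log-OR (on Haldane-corrected
    cells when needed), Fisher p, BH FDR and a significance flag at
    ``fdr < fdr_threshold``.  Significant genes are the cohort's empirical
    predisposition-gene set.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("cohort sizes must be positive")
    case_counts = dict(case_counts)
    control_counts = dict(control_counts)
    genes = sorted(set(case_counts) | set(control_counts))
    rows = []
    for gene in genes:
        k1 = int(case_counts.get(gene, 0))
        k2 = int(control_counts.get(gene, 0))
        if k1 > n_case or k2 > n_control:
            raise ValueError(f"{gene}: carrier count exceeds cohort size")
        rows.append(_enrich_one(gene, k1, n_case, k2, n_control))
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].tolist())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def subtype_stratified_enrichment(cohort: pd.DataFrame, clinical: pd.DataFrame,
                                  control_counts: pd.DataFrame,
                                  subtype: str, genes: list[str],
                                  fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Enrichment restricted to cases of one molecular subtype.

    ``cohort`` carries the ``g_<gene>`` flags keyed by ``patient_id``;
    ``clinical`` supplies the ``subtype`` label; ``control_counts`` has
    columns gene, carriers, n (same controls for every stratum).
    """
    stratum_ids = clinical.loc[clinical["subtype"] == subtype, "patient_id"]
    sub = cohort[cohort["patient_id"].isin(stratum_ids)]
    if sub.empty:
        raise ValueError(f"empty stratum: no patients with subtype {subtype!r}")
    case_counts = {g: int(sub[f"g_{g}"].sum()) for g in genes}
    ctrl = {r.gene: int(r.carriers) for r in control_counts.itertuples()}
    n_control = int(control_counts["n"].iloc[0])
    out = case_control_enrichment(case_counts, {g: ctrl.get(g, 0) for g in genes},
                                  n_case=len(sub), n_control=n_control,
                                  fdr_threshold=fdr_threshold)
    out.insert(0, "subtype", subtype)
    return out


def signed_log_or_matrix(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Heatmap-ready germline x somatic matrix of log10(OR), masked at FDR >= alpha."""
    mat = pairs.pivot(index="germline_gene", columns="somatic_gene", values="log10_or")
    mask = pairs.pivot(index="germline_gene", columns="somatic_gene", values="fdr") >= alpha
    return mat.mask(mask)
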