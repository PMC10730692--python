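"""Germline variant triage: quality filters, consensus pathogenicity, penetrance.

The triage mirrors the curation cascade used for clinical panel germline
calls: sequencing-quality filters first (coverage >= 20x, alternate-allele
depth >= 10, VAF >= 30%), then a two-annotator consensus on the five-level
pathogenicity scale (P / LP / VUS / LB / B).  Variants the two annotators
disagree on are never resolved automatically -- they land in a review queue
(optionally tie-broken by a third annotator's majority vote), since manual
curation is out of scope for software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TriageResult",
    "PenetranceClass",
    "PATHOGENICITY_LABELS",
    "apply_quality_filters",
    "consensus_pathogenicity",
    "assign_penetrance",
    "oncogene_consistent",
    "triage_variants",
    "MIN_DEPTH",
    "MIN_ALT_AD",
    "MIN_VAF",
]

PATHOGENICITY_LABELS = ("P", "LP", "VUS", "LB", "B")
_PATHOGENIC = frozenset({"P", "LP"})
_NOT_PATHOGENIC = frozenset({"VUS", "LB", "B"})

# Quality thresholds, all inclusive ("at least" semantics).
MIN_DEPTH = 20
MIN_ALT_AD = 10
MIN_VAF = 0.30


@dataclass(frozen=True)
class TriageResult:
    """Outcome of triaging one germline variant."""

    status: str  # retained_PLP | excluded_quality | excluded_benign_or_VUS | review_queue
    reason: str


@dataclass(frozen=True)
class PenetranceClass:
    """Relative-risk penetrance tier of a predisposition gene."""

    gene: str
    rr: float | None
    penetrance: str  # high | moderate | low | uncertain | recessive


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def apply_quality_filters(depth, alt_ad, vaf,
                          min_depth: int = MIN_DEPTH,
                          min_alt_ad: int = MIN_ALT_AD,
                          min_vaf: float = MIN_VAF) -> TriageResult:
    """Sequencing-quality gate; the reason names the first failed rule.

    A variant that clears every threshold gets the sentinel status ``pass``
    (it still has to clear the pathogenicity consensus to be retained).
    """
    if _missing(depth) or _missing(alt_ad) or _missing(vaf):
        return TriageResult("excluded_quality", "missing metric")
    if depth < min_depth:
        return TriageResult("excluded_quality", f"coverage {depth} < {min_depth}")
    if alt_ad < min_alt_ad:
        return TriageResult("excluded_quality", f"alt AD {alt_ad} < {min_alt_ad}")
    if vaf < min_vaf:
        return TriageResult("excluded_quality", f"VAF {vaf:.3g} < {min_vaf:.2g}")
    return TriageResult("pass", "quality pass")


def consensus_pathogenicity(annotation_a: str, annotation_b: str,
                            clinvar: str | None = None,
                            third: str | None = None) -> TriageResult:
    """Two-annotator consensus on the five-level pathogenicity scale.

    Retained only when both annotators call P or LP; excluded when both call
    VUS/LB/B; discordant pairs go to the review queue with the ClinVar label
    attached as advisory.  When ``third`` is given, a discordant pair is
    tie-broken by the majority of the three labels (the optional
    third-annotator step); a three-way split still lands in review.
    """
    for lab in (annotation_a, annotation_b) + ((third,) if third else ()):
        if lab not in PATHOGENICITY_LABELS:
            raise ValueError(f"unknown pathogenicity label {lab!r}")
    a_path, b_path = annotation_a in _PATHOGENIC, annotation_b in _PATHOGENIC
    if a_path and b_path:
        return TriageResult("retained_PLP", f"consensus {annotation_a}/{annotation_b}")
    if not a_path and not b_path:
        return TriageResult("excluded_benign_or_VUS", f"consensus {annotation_a}/{annotation_b}")
    if third is not None:
        votes = sum(lab in _PATHOGENIC for lab in (annotation_a, annotation_b, third))
        if votes >= 2:
            return TriageResult("retained_PLP", f"majority with third annotator ({third})")
        return TriageResult("excluded_benign_or_VUS", f"majority with third annotator ({third})")
    advisory = f"; ClinVar: {clinvar}" if clinvar else ""
    return TriageResult("review_queue", f"discordant {annotation_a}/{annotation_b}{advisory}")


def assign_penetrance(gene: str, rr: float | None = None,
                      recessive: bool = False) -> PenetranceClass:
    """Relative-risk penetrance tiers: RR > 5 high, 2-5 moderate, < 2 low.

    Genes without a characterized RR are uncertain; an autosomal-recessive
    condition overrides the RR tier.
    """
    if recessive:
        return PenetranceClass(gene, rr, "recessive")
    if rr is None or (isinstance(rr, float) and np.isnan(rr)):
        return PenetranceClass(gene, None, "uncertain")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if rr > 5:
        tier = "high"
    elif rr >= 2:
        tier = "moderate"
    else:
        tier = "low"
    return PenetranceClass(gene, float(rr), tier)


def oncogene_consistent(gene_role: str, variant_class: str) -> bool:
    """Role-consistency rule: inactivating variants in oncogenes are suspect.

    ``gene_role`` is ``OG`` or ``TSG``; truncating classes (nonsense,
    frameshift, splice) in an oncogene are flagged inconsistent.
    """
    if gene_role == "OG" and variant_class in ("nonsense", "frameshift", "splice"):
        return False
    return True


def triage_variants(variants: pd.DataFrame,
                    gene_roles: dict[str, str] | None = None,
                    use_third_annotator: bool = False,
                    **thresholds) -> pd.DataFrame:
    """Triage a germline variant table; every row gets exactly one status.

    ``variants`` follows the germline interchange schema
    (:data:`bctwohit.io_formats.GERMLINE_COLUMNS`, optionally with a
    ``variant_class`` column for the oncogene-consistency rule and a
    ``annotation_c`` column for the third-annotator tie-break).
    Returns the table with ``status`` and ``reason`` columns appended.
    """
    statuses, reasons = [], []
    for row in variants.itertuples(index=False):
        res = apply_quality_filters(row.depth, row.alt_ad, row.vaf, **thresholds)
        if res.status == "excluded_quality":
            statuses.append(res.status)
            reasons.append(res.reason)
            continue
        third = getattr(row, "annotation_c", None) if use_third_annotator else None
        clinvar = row.clinvar or None
        res = consensus_pathogenicity(row.annotation_a, row.annotation_b,
                                      clinvar=clinvar, third=third or None)
        if res.status == "retained_PLP" and gene_roles is not None:
            vclass = getattr(row, "variant_class", None)
            role = gene_roles.get(row.gene)
            if role and vclass and not oncogene_consistent(role, vclass):
                res = TriageResult("review_queue",
                                   f"inactivating {vclass} variant in oncogene {row.gene}")
        statuses.append(res.status)
        reasons.append(res.reason)
    out = variants.copy()
    out["status"] = statuses
    out["reason"] = reasons
    return out
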