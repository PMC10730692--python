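"""Somatic zygosity inference for pathogenic germline variants.

Given a tumor's purity ``phi``, the allele-specific copy number of the
segment containing a germline variant (total TCN, lesser LCN) and the VAF
observed in tumor reads, the expected VAF of a variant present on ``m`` of
the TCN tumor copies is

    E[VAF] = (phi * m + (1 - phi)) / (phi * TCN + 2 * (1 - phi))

(the admixed normal cells contribute one mutant copy out of two).  Each
candidate zygosity state corresponds to a value of ``m``:

======================  =======================  =========================
state                   mutant copies ``m``      meaning
======================  =======================  =========================
heterozygous            TCN/2 (balanced)         both alleles retained
ASI_two_hit             TCN - LCN (major)        wild-type under-represented
loss_of_WT              TCN, only when LCN = 0   wild-type allele lost
loss_of_mutant          0                        mutant allele lost
======================  =======================  =========================

A state is accepted when the observed VAF falls inside the central
``level`` (default 95%) binomial acceptance interval of its expected VAF at
the observed read depth; the decision cascade below resolves overlaps.
A germline variant coupled with a functional somatic mutation in the same
gene is a compound biallelic (two-hit) event regardless of copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FUNCTIONAL_CLASSES

__all__ = [
    "TumorProfile",
    "ObservedAllele",
    "ZygosityCall",
    "TWO_HIT_STATES",
    "expected_vaf",
    "acceptance_interval",
    "classify_zygosity",
    "detect_biallelic_compound",
    "integrate_compound",
    "summarize_two_hit",
]

#: States counted as two-hit (biallelic) inactivation.
TWO_HIT_STATES = ("ASI_two_hit", "loss_of_WT", "biallelic_compound")
_STATES = ("heterozygous", "ASI_two_hit", "loss_of_WT", "loss_of_mutant",
           "biallelic_compound", "indeterminate")


@dataclass(frozen=True)
class TumorProfile:
    """Purity, ploidy and allele-specific segments for one tumor."""

    sample_id: str
    purity: float | None
    ploidy: float | None
    segments: pd.DataFrame  # columns sample, chrom, start, end, tcn, lcn

    def __post_init__(self):
        if self.purity is not None and not np.isnan(self.purity):
            if not 0 < self.purity <= 1:
                raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    def segment_at(self, chrom, pos) -> tuple[int, int] | None:
        """(TCN, LCN) of the unique segment covering ``pos``, else None."""
        seg = self.segments
        hit = seg[(seg["chrom"].astype(str) == str(chrom))
                  & (seg["start"] <= pos) & (seg["end"] >= pos)]
        if len(hit) > 1:
            raise ValueError(
                f"{self.sample_id}: {len(hit)} overlapping segments at {chrom}:{pos}")
        if hit.empty:
            return None
        row = hit.iloc[0]
        return int(row["tcn"]), int(row["lcn"])


@dataclass(frozen=True)
class ObservedAllele:
    """Alt read count and depth of a germline variant in tumor reads."""

    alt_count: int
    depth: int

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt_count must be in [0, depth]")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class ZygosityCall:
    """Classified two-hit state of one germline variant in one tumor."""

    state: str
    mutant_copies: int | None
    expected_vafs: dict = field(default_factory=dict)
    acceptance_intervals: dict = field(default_factory=dict)
    evidence: str = ""

    def __post_init__(self):
        if self.state not in _STATES:
            raise ValueError(f"unknown zygosity state {self.state!r}")

    @property
    def is_two_hit(self) -> bool:
        return self.state in TWO_HIT_STATES


def expected_vaf(phi: float, m: int, tcn: int) -> float:
    """Expected tumor VAF of a germline variant on ``m`` of ``tcn`` copies.

    At ``phi = 0`` (no tumor DNA in the mix) this reduces to 1/2, the
    germline heterozygous expectation; at ``phi = 1`` it is ``m / tcn``.
    """
    if not 0 <= phi <= 1:
        raise ValueError(f"purity must be in [0, 1], got {phi}")
    if not 0 <= m <= tcn:
        raise ValueError(f"mutant copies m={m} outside [0, TCN={tcn}]")
    denom = phi * tcn + 2.0 * (1.0 - phi)
    if denom == 0:
        raise ValueError("no tumor DNA at locus (TCN = 0 with purity 1)")
    return (phi * m + (1.0 - phi)) / denom


def acceptance_interval(p: float, depth: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail binomial acceptance interval for the observed VAF.

    Returns (lo, hi) as VAF fractions: the alt counts between the
    ``(1-level)/2`` and ``1-(1-level)/2`` exact binomial quantiles of
    Binomial(depth, p), divided by depth.  The interval always contains the
    distribution's central mass and collapses to a point for p in {0, 1}.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lo = stats.binom.ppf(alpha / 2.0, depth, p)
    hi = stats.binom.ppf(1.0 - alpha / 2.0, depth, p)
    # ppf returns -1-free floats; degenerate p handled naturally (ppf -> 0 or n)
    return float(lo) / depth, float(hi) / depth


def _balanced_hypotheses(tcn: int) -> list[int]:
    """Mutant copy counts consistent with balanced heterozygosity.

    Even TCN has the single balanced state m = TCN/2; odd TCN >= 3 is
    evaluated at both nearest-balanced states floor and ceil of TCN/2.
    A locus with fewer than two tumor copies cannot be heterozygous, so
    TCN < 2 has no balanced hypothesis.
    """
    if tcn < 2:
        return []
    if tcn % 2 == 0:
        return [tcn // 2]
    return [tcn // 2, tcn // 2 + 1]


def classify_zygosity(obs: ObservedAllele,
                      tumor: TumorProfile,
                      chrom,
                      pos: int,
                      genotype_homozygous: bool = False,
                      level: float = 0.95) -> ZygosityCall:
    """Classify the somatic zygosity of one germline variant.

    Decision cascade (first matching rule wins):

    0. no covering segment, missing purity, or homozygous germline call
       -> ``indeterminate``;
    1. build the hypothesis set (balanced, loss of wild type when LCN = 0,
       loss of mutant, mutant-on-major imbalance);
    2. VAF inside the balanced interval, or below its lower bound while
       TCN > 2 (gain diluting the variant) -> ``heterozygous``;
    3. LCN = 0 and VAF inside-or-above the loss-of-wild-type interval
       -> ``loss_of_WT``;
    4. VAF inside-or-below the loss-of-mutant (m = 0) interval
       -> ``loss_of_mutant``;
    5. VAF inside-or-above the mutant-on-major interval (m = TCN - LCN,
       only when the major allele genuinely exceeds the minor)
       -> ``ASI_two_hit``;
    6. among balanced sub-hypotheses the reported ``m`` maximizes the
       binomial likelihood of the observed alt count;
    7. nothing accepted -> ``indeterminate`` (discordant VAF).
    """
    if obs.depth < 1:
        raise ValueError("observed depth must be >= 1")
    if genotype_homozygous:
        return ZygosityCall("indeterminate", None, {}, {}, "germline homozygous")
    if tumor.purity is None or (isinstance(tumor.purity, float) and np.isnan(tumor.purity)):
        return ZygosityCall("indeterminate", None, {}, {}, "tumor purity unavailable")
    cn = tumor.segment_at(chrom, pos)
    if cn is None:
        return ZygosityCall("indeterminate", None, {}, {}, "no copy-number segment at locus")
    tcn, lcn = cn
    phi = float(tumor.purity)
    if tcn == 0 and phi == 1.0:
        return ZygosityCall("indeterminate", None, {}, {},
                            "no tumor DNA at locus (TCN = 0, purity 1)")
    vaf = obs.vaf

    expected: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}

    def hyp(name: str, m: int) -> tuple[float, float]:
        p = expected_vaf(phi, m, tcn)
        ci = acceptance_interval(p, obs.depth, level)
        expected[name] = p
        intervals[name] = ci
        return ci

    bal_ms = [m for m in _balanced_hypotheses(tcn) if m <= tcn]
    bal_cis = {m: hyp(f"balanced_m{m}", m) for m in bal_ms}

    def likelihood(m: int) -> float:
        return stats.binom.pmf(obs.alt_count, obs.depth, expected_vaf(phi, m, tcn))

    # (2) balanced heterozygosity, or dilution by a gain
    accepted_bal = [m for m, (lo, hi) in bal_cis.items() if lo <= vaf <= hi]
    if accepted_bal:
        m_hat = max(accepted_bal, key=likelihood)
        return ZygosityCall("heterozygous", m_hat, expected, intervals,
                            f"VAF {vaf:.3f} within balanced interval (m={m_hat})")
    if bal_cis and tcn > 2 and vaf < min(lo for lo, _ in bal_cis.values()):
        m_hat = min(bal_ms)
        return ZygosityCall("heterozygous", m_hat, expected, intervals,
                            f"VAF {vaf:.3f} below balanced interval under gain (TCN={tcn})")

    # (3) loss of the wild-type allele (copy-neutral or deletion LOH)
    if lcn == 0 and tcn >= 1:
        lo, hi = hyp("loss_of_WT", tcn)
        if vaf >= lo:
            return ZygosityCall("loss_of_WT", tcn, expected, intervals,
                                f"VAF {vaf:.3f} >= {lo:.3f} under LCN=0")

    # (4) loss of the mutant allele
    lo, hi = hyp("loss_of_mutant", 0)
    if vaf <= hi:
        return ZygosityCall("loss_of_mutant", 0, expected, intervals,
                            f"VAF {vaf:.3f} <= {hi:.3f} under m=0")

    # (5) allele-specific imbalance with the mutant on the major allele
    m_major = tcn - lcn
    if m_major > lcn:
        lo, hi = hyp("mutant_on_major", m_major)
        if vaf >= lo:
            return ZygosityCall("ASI_two_hit", m_major, expected, intervals,
                                f"VAF {vaf:.3f} >= {lo:.3f} under m={m_major}")

    return ZygosityCall("indeterminate", None, expected, intervals, "discordant VAF")


def detect_biallelic_compound(patient_id: str, gene: str,
                              somatic: pd.DataFrame) -> bool:
    """True iff the patient carries a functional somatic mutation in ``gene``.

    Functional classes are missense, nonsense, frameshift and splice;
    silent and other mutations never count as a second hit.
    """
    hits = somatic[(somatic["sample"] == patient_id)
                   & (somatic["gene"] == gene)
                   & somatic["variant_class"].isin(FUNCTIONAL_CLASSES)]
    return len(hits) > 0


def integrate_compound(call: ZygosityCall, has_compound_hit: bool) -> ZygosityCall:
    """Fold a same-gene somatic hit into a copy-number-based zygosity call.

    Copy-number two-hit states (ASI, loss of WT) are kept -- the somatic hit
    is recorded as corroborating evidence; every other state becomes
    ``biallelic_compound`` because the somatic mutation itself is the
    second hit.
    """
    if not has_compound_hit:
        return call
    if call.state in ("ASI_two_hit", "loss_of_WT"):
        return ZygosityCall(call.state, call.mutant_copies, call.expected_vafs,
                            call.acceptance_intervals,
                            call.evidence + "; plus same-gene somatic hit")
    return ZygosityCall("biallelic_compound", call.mutant_copies,
                        call.expected_vafs, call.acceptance_intervals,
                        "functional somatic mutation in same gene")


def summarize_two_hit(calls: pd.DataFrame,
                      gene_sets: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-gene (and per-gene-set) two-hit fractions.

    ``calls`` needs columns ``gene`` and ``state``.  The two-hit fraction is
    two-hit calls / classifiable calls, where indeterminate calls are not
    classifiable; a gene with no classifiable call reports NA.
    """
    if calls.empty:
        raise ValueError("no zygosity calls to summarize")

    def _one(label: str, sub: pd.DataFrame) -> dict:
        classifiable = (sub["state"] != "indeterminate").sum()
        two_hit = sub["state"].isin(TWO_HIT_STATES).sum()
        frac = two_hit / classifiable if classifiable else np.nan
        return {"group": label, "n_variants": len(sub),
                "n_classifiable": int(classifiable), "n_two_hit": int(two_hit),
                "two_hit_fraction": frac}

    rows = [_one(gene, sub) for gene, sub in calls.groupby("gene", sort=True)]
    if gene_sets:
        for name, genes in gene_sets.items():
            rows.append(_one(name, calls[calls["gene"].isin(genes)]))
    return pd.DataFrame(rows, columns=["group", "n_variants", "n_classifiable",
                                       "n_two_hit", "two_hit_fraction"])
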