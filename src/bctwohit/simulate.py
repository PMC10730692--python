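"""Synthetic cohort generator with full ground truth.

Emulates the statistical structure of a matched tumor-blood panel-sequencing
breast-cancer cohort: per-gene germline carrier frequencies on the order of
the observed carrier spectrum (BRCA2 2.5%, BRCA1 2.2%, PALB2 0.9%, ...),
clinical covariates with realistic marginals, carrier status coupled to the
covariates through the published carrier-risk logistic coefficients, somatic
functional-mutation flags with configurable pairwise log-odds interactions,
and -- for each carrier -- a tumor with purity, allele-specific copy-number
segments drawn from per-state templates, and binomially sampled alt reads at
panel depth.  Every latent draw is recorded in truth tables so downstream
recovery tests never peek at the generator internals.

A single global seed fans out deterministically (``numpy.random.SeedSequence``
spawning) to per-component generators, so adding a later stage never perturbs
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import riskmodel
from .hrd import MB, GenomeBuild, toy_genome
from .zygosity import expected_vaf

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_reads",
    "simulate_cohort",
    "simulate_segment_genome",
    "STATE_TEMPLATES",
    "GENE_LOCI",
]

#: (TCN, LCN, mutant copies m) used to draw tumor reads for each planted state.
STATE_TEMPLATES = {
    "heterozygous": (2, 1, 1),
    "ASI_two_hit": (4, 1, 3),
    "loss_of_WT": (2, 0, 2),
    "loss_of_mutant": (1, 0, 0),
    "biallelic_compound": (2, 1, 1),  # balanced VAF; the somatic hit is the 2nd hit
}

#: Toy-genome chromosome and q-arm position assigned to each panel gene.
GENE_LOCI = {
    "BRCA1": ("chr17", 80 * MB), "BRCA2": ("chr13", 80 * MB),
    "PALB2": ("chr16", 80 * MB), "CHEK2": ("chr22", 80 * MB),
    "TP53": ("chr17", 90 * MB), "ATM": ("chr11", 80 * MB),
    "MUTYH": ("chr1", 80 * MB), "PTEN": ("chr10", 80 * MB),
    "PIK3CA": ("chr3", 80 * MB), "GATA3": ("chr10", 90 * MB),
}

_DEFAULT_GERMLINE_FREQ = {
    "BRCA2": 0.025, "BRCA1": 0.022, "PALB2": 0.009, "MUTYH": 0.006,
    "CHEK2": 0.004, "ATM": 0.003, "TP53": 0.002,
}
_DEFAULT_SOMATIC_FREQ = {
    "TP53": 0.50, "PIK3CA": 0.30, "GATA3": 0.10, "BRCA2": 0.03, "BRCA1": 0.028,
}
_DEFAULT_TWO_HIT = {
    "BRCA1": 0.76, "BRCA2": 0.77, "PALB2": 0.59, "CHEK2": 0.35,
    "TP53": 0.89, "MUTYH": 0.35, "ATM": 0.35,
}
_DEFAULT_INTERACTIONS = {
    ("BRCA1", "TP53"): 1.2,     # co-occurrence
    ("BRCA1", "PIK3CA"): -1.5,  # mutual exclusivity
    ("MUTYH", "BRCA1"): 1.0,
}
_BCDG = ("BRCA1", "BRCA2", "CHEK2", "PALB2", "TP53")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_patients: int = 4000
    germline_frequencies: dict = field(default_factory=lambda: dict(_DEFAULT_GERMLINE_FREQ))
    somatic_frequencies: dict = field(default_factory=lambda: dict(_DEFAULT_SOMATIC_FREQ))
    bcdg_genes: tuple = _BCDG
    carrier_model: riskmodel.RiskModelSpec | None = None  # default: published calculator
    interaction_log_or: dict = field(default_factory=lambda: dict(_DEFAULT_INTERACTIONS))
    two_hit_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_TWO_HIT))
    two_hit_state_weights: dict = field(default_factory=lambda: {
        "ASI_two_hit": 0.60, "loss_of_WT": 0.25, "biallelic_compound": 0.15})
    non_two_hit_state_weights: dict = field(default_factory=lambda: {
        "heterozygous": 0.90, "loss_of_mutant": 0.10})
    purity_range: tuple = (0.4, 0.9)
    tumor_depth: int = 500
    germline_depth: int = 200
    covariate_missing_rate: float = 0.03
    hrd_counts_two_hit: tuple = (3, 2, 4)   # planted (NtAI, LOH, LST) in two-hit tumors
    hrd_counts_other: tuple = (1, 0, 1)
    decoy_benign_fraction: float = 0.02     # benign/VUS decoy germline calls per patient
    decoy_lowqual_fraction: float = 0.01    # low-quality decoy calls per patient
    discordant_fraction: float = 0.005      # discordant-annotation decoys (review queue)

    def __post_init__(self):
        for g, f in self.germline_frequencies.items():
            if not 0 <= f <= 1:
                raise ValueError(f"carrier frequency of {g} outside [0, 1]")


@dataclass(frozen=True)
class SimulatedCohort:
    """Generator output: analysis-ready inputs plus ground-truth tables."""

    cohort: pd.DataFrame       # patients x carrier/somatic flags (+ subtype)
    clinical: pd.DataFrame     # clinical covariates with planted missingness
    germline: pd.DataFrame     # VCF-like germline call table (incl. decoys)
    somatic: pd.DataFrame      # MAF-like somatic mutation table
    segments: pd.DataFrame     # SEG-like allele-specific segments per sample
    purity: pd.DataFrame       # sample, purity, ploidy
    genome: GenomeBuild
    truth: dict                # ground-truth tables keyed by name


def simulate_reads(true_state: str, phi: float, depth: int, tcn: int, lcn: int,
                   seed) -> tuple[int, int]:
    """Binomially sampled (alt_count, depth) for one variant in one tumor."""
    if true_state not in STATE_TEMPLATES:
        raise ValueError(f"invalid zygosity state {true_state!r}")
    m = {"heterozygous": max(tcn // 2, min(1, tcn)),
         "ASI_two_hit": tcn - lcn,
         "loss_of_WT": tcn,
         "loss_of_mutant": 0,
         "biallelic_compound": max(tcn // 2, min(1, tcn))}[true_state]
    p = expected_vaf(phi, m, tcn)
    rng = np.random.default_rng(seed)
    return int(rng.binomial(depth, p)), depth


def _interaction_cell_probs(q: float, f: float, log_or: float) -> tuple[float, float]:
    """P(somatic | germline carrier), P(somatic | non-carrier) matching the
    marginals (q, f) and the planted odds ratio exp(log_or).

    Any finite log-OR is attainable when both marginals lie strictly inside
    (0, 1); a degenerate marginal leaves the odds ratio undefined.
    """
    if not (0 < q < 1 and 0 < f < 1):
        raise ValueError(f"infeasible log-OR {log_or} for marginals ({q}, {f})")
    theta = float(np.exp(log_or))
    if abs(theta - 1.0) < 1e-12:
        return f, f
    s = 1.0 + (q + f) * (theta - 1.0)
    disc = s * s - 4.0 * theta * (theta - 1.0) * q * f
    if disc < 0:
        raise ValueError(f"infeasible log-OR {log_or} for marginals ({q}, {f})")
    p11 = (s - np.sqrt(disc)) / (2.0 * (theta - 1.0))
    p1, p0 = p11 / q, (f - p11) / (1.0 - q)
    if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
        raise ValueError(f"infeasible log-OR {log_or} for marginals ({q}, {f})")
    return p1, p0


def _draw_covariates(rng, n: int) -> pd.DataFrame:
    """Clinical covariates with marginals typical of an Asian surgical cohort."""
    age = np.round(np.clip(rng.normal(49, 11, n), 22, 90), 1)
    ki67 = np.round(100 * rng.beta(1.8, 3.5, n), 1)
    grade = rng.choice([1, 2, 3], n, p=[0.15, 0.55, 0.30])
    t_cat = rng.choice([0, 1, 2, 3, 4], n, p=[0.05, 0.45, 0.40, 0.07, 0.03])
    n_cat = rng.choice([0, 1, 2, 3], n, p=[0.55, 0.27, 0.11, 0.07])
    m_cat = rng.binomial(1, 0.05, n)
    er = rng.binomial(1, 0.65, n)
    pr = rng.binomial(1, 0.58, n)
    her2 = rng.binomial(1, 0.25, n)
    contral = rng.binomial(1, 0.015, n)
    fhbc = rng.binomial(1, 0.06, n)
    fhoc = rng.binomial(1, 0.01, n)
    other = rng.binomial(1, 0.12, n)
    subtype = np.where(her2 == 1, "HER2+",
                       np.where((er == 1) | (pr == 1), "HR+/HER2-", "TNBC"))
    return pd.DataFrame({
        "age": age, "grade": grade, "T": t_cat, "N": n_cat, "M": m_cat,
        "ER": er, "PR": pr, "HER2": her2, "Ki67": ki67,
        "contralateral": contral, "FHBC": fhbc, "FHOC": fhoc,
        "other_cancer_history": other, "subtype": subtype,
    })


def simulate_segment_genome(n_ntai: int, n_loh: int, n_lst: int,
                            genome: GenomeBuild | None = None,
                            seed=0,
                            skip_chroms: tuple = ()) -> pd.DataFrame:
    """Segment profile whose HRD components equal the planted counts exactly.

    Each planted event occupies a dedicated chromosome and is built so it
    triggers exactly one component: a telomeric-AI event fills a whole p-arm
    with an unbalanced state (the centromere boundary is never an LST), an
    LOH event is a 16 Mb interstitial LCN=0 run buffered by sub-10 Mb spacer
    segments, and an LST event is a single mid-arm transition between two
    balanced states.  Chromosomes in ``skip_chroms`` are left untouched (the
    caller may place variant-locus segments there); remaining chromosomes
    are emitted as single balanced-diploid segments.  Raises when the counts
    exceed the genome's capacity.
    """
    if genome is None:
        genome = toy_genome()
    if min(n_ntai, n_loh, n_lst) < 0:
        raise ValueError("planted counts must be non-negative")
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome.chrom_length if c not in set(skip_chroms)]
    n_events = n_ntai + n_loh + n_lst
    if n_events > len(chroms):
        raise ValueError(
            f"planted counts ({n_ntai}, {n_loh}, {n_lst}) exceed genome capacity "
            f"of {len(chroms)} event chromosomes")
    events = (["ntai"] * n_ntai + ["loh"] * n_loh + ["lst"] * n_lst)
    events += ["none"] * (len(chroms) - n_events)
    rows = []
    for chrom, event in zip(chroms, events):
        length = genome.chrom_length[chrom]
        cs, ce = genome.centromere[chrom]
        if event == "ntai":
            # whole p-arm unbalanced gain; q-arm balanced diploid.  The state
            # change sits across the centromere, so no LST is created.
            rows.append((chrom, 1, cs - 1, 3, 1))
            rows.append((chrom, cs, length, 2, 1))
        elif event == "loh":
            # interstitial 16 Mb LOH on the q-arm, buffered by 5 Mb spacers so
            # every breakpoint has a sub-10 Mb flank (no LST).
            start = ce + 1 + int(rng.integers(0, 5)) * MB
            a = start + 20 * MB
            b = a + 5 * MB
            c = b + 16 * MB
            d = c + 5 * MB
            rows.append((chrom, 1, a - 1, 2, 1))
            rows.append((chrom, a, b - 1, 3, 2))
            rows.append((chrom, b, c - 1, 1, 0))
            rows.append((chrom, c, d - 1, 3, 2))
            rows.append((chrom, d, length, 2, 1))
        elif event == "lst":
            # one balanced-state transition mid q-arm; both flanks >= 10 Mb,
            # neither allelically imbalanced, no LOH.
            bp = ce + 20 * MB + int(rng.integers(0, 10)) * MB
            rows.append((chrom, 1, bp - 1, 2, 1))
            rows.append((chrom, bp, length, 4, 2))
        else:
            rows.append((chrom, 1, length, 2, 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tcn", "lcn"])


def _pick(rng, weights: dict) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with ground truth.

    The carrier indicator is drawn from the carrier-risk logistic model on
    the drawn covariates (so the refit machinery can recover the printed
    coefficients); the carrier's gene is then assigned with probability
    proportional to the configured per-gene frequencies.  Somatic flags are
    Bernoulli at their marginal frequencies except where a pairwise
    germline-somatic log-OR is planted, in which case the conditional
    probabilities are solved in closed form from the marginals and the OR.
    """
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    (covariate_seed, carrier_seed, somatic_seed, tumor_seed,
     decoy_seed, missing_seed) = ss.spawn(6)
    genome = toy_genome()
    carrier_model = config.carrier_model or riskmodel.bcdg_model()

    # --- covariates and carrier status -------------------------------------
    rng_cov = np.random.default_rng(covariate_seed)
    clinical = _draw_covariates(rng_cov, n)
    clinical.insert(0, "patient_id", [f"P{i:05d}" for i in range(n)])

    rng_car = np.random.default_rng(carrier_seed)
    p_carrier = carrier_model.predict_proba(clinical)
    is_carrier = rng_car.random(n) < p_carrier
    model_genes = [g for g in config.germline_frequencies if g in config.bcdg_genes]
    other_genes = [g for g in config.germline_frequencies if g not in config.bcdg_genes]
    shares = np.array([config.germline_frequencies[g] for g in model_genes], dtype=float)
    shares = shares / shares.sum()
    gene_of_carrier = np.array([
        model_genes[rng_car.choice(len(model_genes), p=shares)] if c else ""
        for c in is_carrier], dtype=object)
    germ_flags = {g: (gene_of_carrier == g) for g in model_genes}
    for g in other_genes:  # non-model genes: independent Bernoulli marginals
        germ_flags[g] = rng_car.random(n) < config.germline_frequencies[g]

    mean_p = float(np.mean(p_carrier))
    gene_marginals = {g: mean_p * s for g, s in zip(model_genes, shares)}
    gene_marginals.update({g: config.germline_frequencies[g] for g in other_genes})

    # --- somatic functional-mutation flags ---------------------------------
    rng_som = np.random.default_rng(somatic_seed)
    influenced = {}
    for (g_gene, s_gene), lor in config.interaction_log_or.items():
        if s_gene in influenced:
            raise ValueError(f"somatic gene {s_gene} appears in two planted interactions")
        influenced[s_gene] = (g_gene, lor)
    som_flags = {}
    for s_gene, f in config.somatic_frequencies.items():
        if s_gene in influenced:
            g_gene, lor = influenced[s_gene]
            q = gene_marginals.get(g_gene)
            if q is None:
                raise ValueError(f"planted interaction names unknown germline gene {g_gene}")
            try:
                p1, p0 = _interaction_cell_probs(q, f, lor)
            except ValueError as exc:
                raise ValueError(f"pair ({g_gene}, {s_gene}): {exc}") from None
            carrier_vec = np.asarray(germ_flags[g_gene])
            probs = np.where(carrier_vec, p1, p0)
        else:
            probs = np.full(n, f)
        som_flags[s_gene] = rng_som.random(n) < probs

    cohort = pd.DataFrame({"patient_id": clinical["patient_id"]})
    for g in sorted(germ_flags):
        cohort[f"g_{g}"] = np.asarray(germ_flags[g], dtype=bool)
    for s in sorted(som_flags):
        cohort[f"s_{s}"] = np.asarray(som_flags[s], dtype=bool)
    cohort["subtype"] = clinical["subtype"]

    # --- per-carrier tumors: states, segments, reads -----------------------
    rng_tum = np.random.default_rng(tumor_seed)
    germline_rows, somatic_rows, segment_frames, purity_rows = [], [], [], []
    truth_variants = []
    lo, hi = config.purity_range
    carriers_any = sorted(set(np.flatnonzero(is_carrier))
                          | {i for g in other_genes for i in np.flatnonzero(germ_flags[g])})
    for i in carriers_any:
        pid = clinical.loc[i, "patient_id"]
        genes_i = [g for g in germ_flags if germ_flags[g][i]]
        phi = float(rng_tum.uniform(lo, hi))
        ploidy = float(rng_tum.choice([2.0, 2.0, 2.0, 3.2, 2.4]))
        two_hit_any = False
        gene_states = []
        for gene in genes_i:
            f2 = config.two_hit_fractions.get(gene, 0.35)
            if rng_tum.random() < f2:
                state = _pick(rng_tum, config.two_hit_state_weights)
            else:
                state = _pick(rng_tum, config.non_two_hit_state_weights)
            gene_states.append((gene, state))
            two_hit_any |= state in ("ASI_two_hit", "loss_of_WT", "biallelic_compound")

        k1, k2, k3 = (config.hrd_counts_two_hit if two_hit_any
                      else config.hrd_counts_other)
        variant_chroms = tuple({GENE_LOCI[g][0] for g, _ in gene_states})
        seg = simulate_segment_genome(k1, k2, k3, genome,
                                      seed=rng_tum.integers(2 ** 31),
                                      skip_chroms=variant_chroms)
        extra = []
        for gene, state in gene_states:
            chrom, pos = GENE_LOCI[gene]
            tcn, lcn, m = STATE_TEMPLATES[state]
            extra.append((chrom, 1, genome.chrom_length[chrom], tcn, lcn))
            depth_t = max(int(rng_tum.poisson(config.tumor_depth)), 50)
            alt_t = int(rng_tum.binomial(depth_t, expected_vaf(phi, m, tcn)))
            depth_n = max(int(rng_tum.poisson(config.germline_depth)), 30)
            alt_n = int(rng_tum.binomial(depth_n, 0.5))
            ann = ("P", "P") if rng_tum.random() < 0.7 else ("P", "LP")
            germline_rows.append({
                "patient_id": pid, "gene": gene, "chrom": chrom, "pos": pos,
                "ref": "G", "alt": "A", "depth": depth_n, "alt_ad": alt_n,
                "vaf": round(alt_n / depth_n, 6), "genotype_homozygous": False,
                "annotation_a": ann[0], "annotation_b": ann[1], "clinvar": "P",
                "tumor_depth": depth_t, "tumor_alt": alt_t,
            })
            truth_variants.append({
                "patient_id": pid, "gene": gene, "true_state": state,
                "purity": phi, "tcn": tcn, "lcn": lcn, "mutant_copies": m,
                "tumor_depth": depth_t, "tumor_alt": alt_t,
                "expected_vaf": expected_vaf(phi, m, tcn),
                "two_hit": state in ("ASI_two_hit", "loss_of_WT", "biallelic_compound"),
            })
            if state == "biallelic_compound":
                somatic_rows.append({
                    "sample": pid, "gene": gene,
                    "variant_class": str(rng_tum.choice(
                        ["missense", "nonsense", "frameshift", "splice"])),
                    "chrom": chrom, "pos": pos + 1000, "ref": "C", "alt": "T",
                    "functional": True,
                })
        # variant chromosomes may host several genes; deduplicate whole-chrom rows
        seen = set()
        for row in extra:
            if row[0] not in seen:
                seen.add(row[0])
                seg = pd.concat([seg[seg["chrom"] != row[0]],
                                 pd.DataFrame([row], columns=seg.columns)],
                                ignore_index=True)
        seg.insert(0, "sample", pid)
        segment_frames.append(seg)
        purity_rows.append({"sample": pid, "purity": round(phi, 4),
                            "ploidy": ploidy,
                            "two_hit_any": two_hit_any,
                            "ntai": k1, "loh": k2, "lst": k3})

    # Gene-level somatic flag rows (one mutation per flagged sample-gene).
    # The planted zygosity state defines a carrier's same-gene somatic status,
    # so a functional somatic hit is never emitted in a gene whose planted
    # state is not biallelic_compound (and always is when it is).
    blocked = {(t["patient_id"], t["gene"]) for t in truth_variants
               if t["true_state"] != "biallelic_compound"}
    forced = {(t["patient_id"], t["gene"]) for t in truth_variants
              if t["true_state"] == "biallelic_compound"}
    for s_gene, flags in som_flags.items():
        chrom, pos = GENE_LOCI.get(s_gene, ("chr2", 80 * MB))
        flags = np.asarray(flags).copy()
        for i in range(n):
            pid = clinical.loc[i, "patient_id"]
            if (pid, s_gene) in blocked:
                flags[i] = False
            elif (pid, s_gene) in forced:
                flags[i] = True
        som_flags[s_gene] = flags
        cohort[f"s_{s_gene}"] = flags
        for i in np.flatnonzero(flags):
            pid = clinical.loc[i, "patient_id"]
            if (pid, s_gene) in forced:
                continue  # the compound hit itself was already emitted
            somatic_rows.append({
                "sample": pid, "gene": s_gene,
                "variant_class": "missense", "chrom": chrom, "pos": pos + 5000,
                "ref": "A", "alt": "G", "functional": True,
            })

    # --- decoy germline calls for the curation stage -----------------------
    rng_dec = np.random.default_rng(decoy_seed)
    decoys = []
    for kind, frac in (("benign", config.decoy_benign_fraction),
                       ("lowqual", config.decoy_lowqual_fraction),
                       ("discordant", config.discordant_fraction)):
        k = rng_dec.binomial(n, frac)
        for i in rng_dec.choice(n, size=k, replace=False):
            pid = clinical.loc[int(i), "patient_id"]
            if kind == "benign":
                ann = tuple(rng_dec.choice(["VUS", "LB", "B"], size=2))
                depth_n, alt_n = 150, 75
            elif kind == "lowqual":
                ann = ("P", "P")
                depth_n, alt_n = 15, 7
            else:
                ann = ("P", "VUS")
                depth_n, alt_n = 150, 75
            decoys.append({
                "patient_id": pid, "gene": "ATM", "chrom": "chr11", "pos": 81 * MB,
                "ref": "T", "alt": "C", "depth": depth_n, "alt_ad": alt_n,
                "vaf": round(alt_n / depth_n, 6), "genotype_homozygous": False,
                "annotation_a": ann[0], "annotation_b": ann[1],
                "clinvar": "VUS" if kind != "lowqual" else "P",
                "tumor_depth": 150, "tumor_alt": 75,
            })

    from .io_formats import GERMLINE_COLUMNS
    germline = pd.DataFrame(germline_rows + decoys, columns=GERMLINE_COLUMNS)
    somatic = pd.DataFrame(somatic_rows,
                           columns=["sample", "gene", "variant_class", "chrom",
                                    "pos", "ref", "alt", "functional"])
    segments = (pd.concat(segment_frames, ignore_index=True)
                if segment_frames else
                pd.DataFrame(columns=["sample", "chrom", "start", "end", "tcn", "lcn"]))
    segments = segments.sort_values(["sample", "chrom", "start"]).reset_index(drop=True)
    purity = pd.DataFrame(purity_rows)

    # --- planted covariate missingness -------------------------------------
    rng_mis = np.random.default_rng(missing_seed)
    clinical_missing = clinical.copy()
    if config.covariate_missing_rate > 0:
        for col in ("Ki67", "grade", "N"):
            holes = rng_mis.random(n) < config.covariate_missing_rate
            clinical_missing.loc[holes, col] = np.nan

    truth = {
        "variants": pd.DataFrame(truth_variants),
        "carrier": pd.DataFrame({"patient_id": clinical["patient_id"],
                                 "bcdg_carrier": is_carrier,
                                 "p_carrier": p_carrier}),
        "gene_marginals": pd.Series(gene_marginals, name="marginal"),
        "tumors": purity[["sample", "two_hit_any", "ntai", "loh", "lst"]].copy()
        if not purity.empty else pd.DataFrame(),
        "clinical_complete": clinical,
    }
    purity_out = (purity[["sample", "purity", "ploidy"]].copy()
                  if not purity.empty else
                  pd.DataFrame(columns=["sample", "purity", "ploidy"]))
    return SimulatedCohort(cohort=cohort, clinical=clinical_missing,
                           germline=germline, somatic=somatic, segments=segments,
                           purity=purity_out, genome=genome, truth=truth)
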