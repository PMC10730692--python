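"""End-to-end orchestration of the analysis stages with deterministic re-runs.

Stage order: germline curation -> zygosity/two-hit -> HRD -> germline-somatic
interactions -> case-control enrichment -> risk modelling.  Every run writes
a manifest recording the package version, seed, a hash of the configuration
and per-stage record counts (in = out + rejected), so identical configs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, curation, hrd, io_formats, riskmodel, zygosity
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("bctwohit")

__all__ = ["PipelineConfig", "run_pipeline", "write_simulated_inputs"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles of one pipeline run."""

    germline: str
    somatic: str
    segments: str
    purity: str
    clinical: str
    control_counts: str | None = None
    out_dir: str = "bctwohit_run"
    seed: int = 0
    # thresholds
    min_depth: int = 20
    min_alt_ad: int = 10
    min_vaf: float = 0.30
    ci_level: float = 0.95
    fdr_threshold: float = 0.05
    # stage toggles
    run_curation: bool = True
    run_zygosity: bool = True
    run_hrd: bool = True
    run_interactions: bool = True
    run_case_control: bool = True
    run_risk: bool = True

    def validate(self) -> None:
        for name in ("germline", "somatic", "segments", "purity", "clinical"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where its outputs land
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _zygosity_stage(retained: pd.DataFrame, somatic: pd.DataFrame,
                    segments: pd.DataFrame, purity: pd.DataFrame,
                    level: float) -> pd.DataFrame:
    purity_map = {r.sample: (r.purity, r.ploidy) for r in purity.itertuples()}
    rows = []
    for v in retained.itertuples(index=False):
        pid = v.patient_id
        phi, ploidy = purity_map.get(pid, (np.nan, np.nan))
        profile = zygosity.TumorProfile(
            pid, None if np.isnan(phi) else float(phi),
            None if np.isnan(ploidy) else float(ploidy),
            segments[segments["sample"] == pid])
        if np.isnan(v.tumor_depth) or v.tumor_depth < 1:
            call = zygosity.ZygosityCall("indeterminate", None, {}, {},
                                         "no tumor read observation")
        else:
            obs = zygosity.ObservedAllele(int(v.tumor_alt), int(v.tumor_depth))
            call = zygosity.classify_zygosity(obs, profile, v.chrom, int(v.pos),
                                              genotype_homozygous=v.genotype_homozygous,
                                              level=level)
            call = zygosity.integrate_compound(
                call, zygosity.detect_biallelic_compound(pid, v.gene, somatic))
        log.debug("zygosity %s %s -> %s", pid, v.gene, call.state)
        rows.append({
            "patient_id": pid, "gene": v.gene, "chrom": v.chrom, "pos": v.pos,
            "state": call.state, "mutant_copies": call.mutant_copies,
            "two_hit": call.is_two_hit,
            "expected_vafs": json.dumps({k: round(x, 6) for k, x in call.expected_vafs.items()}),
            "acceptance_intervals": json.dumps(
                {k: [round(a, 6), round(b, 6)] for k, (a, b) in call.acceptance_intervals.items()}),
            "evidence": call.evidence,
        })
    return pd.DataFrame(rows, columns=["patient_id", "gene", "chrom", "pos", "state",
                                       "mutant_copies", "two_hit", "expected_vafs",
                                       "acceptance_intervals", "evidence"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": config.config_hash(), "stages": {}}

    germline = io_formats.read_germline_table(config.germline)
    somatic = io_formats.read_somatic_maf(config.somatic)
    segments = io_formats.read_segments(config.segments)
    purity = io_formats.read_purity(config.purity)
    clinical = io_formats.read_clinical(config.clinical)

    # --- curation ----------------------------------------------------------
    if config.run_curation:
        triaged = curation.triage_variants(germline, min_depth=config.min_depth,
                                           min_alt_ad=config.min_alt_ad,
                                           min_vaf=config.min_vaf)
        retained = triaged[triaged["status"] == "retained_PLP"]
        io_formats.write_table(triaged.drop(columns=["tumor_depth", "tumor_alt"]),
                               out / "curation.tsv")
        io_formats.write_table(
            triaged[triaged["status"] == "review_queue"]
            .drop(columns=["tumor_depth", "tumor_alt"]),
            out / "review_queue.tsv")
        manifest["stages"]["curation"] = {
            "in": len(germline), "out": int(len(retained)),
            "rejected": int(len(germline) - len(retained)),
            "by_status": triaged["status"].value_counts().to_dict()}
    else:
        retained = germline.copy()
        manifest["stages"]["curation"] = {"skipped": True}

    # --- zygosity ----------------------------------------------------------
    if config.run_zygosity:
        calls = _zygosity_stage(retained, somatic, segments, purity, config.ci_level)
        io_formats.write_table(calls, out / "zygosity.tsv")
        summary = (zygosity.summarize_two_hit(calls) if len(calls)
                   else pd.DataFrame(columns=["group", "n_variants", "n_classifiable",
                                              "n_two_hit", "two_hit_fraction"]))
        io_formats.write_table(summary, out / "two_hit_summary.tsv")
        manifest["stages"]["zygosity"] = {
            "in": int(len(retained)), "out": int(len(calls)), "rejected": 0,
            "two_hit": int(calls["two_hit"].sum()) if len(calls) else 0}
    else:
        calls = pd.DataFrame(columns=["patient_id", "gene", "state", "two_hit"])
        manifest["stages"]["zygosity"] = {"skipped": True}

    # --- HRD ---------------------------------------------------------------
    if config.run_hrd:
        genome = hrd.toy_genome()
        table = hrd.hrd_table(segments, purity, genome)
        io_formats.write_table(table, out / "hrd.tsv")
        manifest["stages"]["hrd"] = {"in": int(segments["sample"].nunique()),
                                     "out": int(len(table)), "rejected": 0}
    else:
        manifest["stages"]["hrd"] = {"skipped": True}

    # --- cohort flags for association stages -------------------------------
    patients = clinical["patient_id"]
    germ_genes = sorted(retained["gene"].unique())
    som_genes = sorted(somatic.loc[somatic["functional"], "gene"].unique())
    cohort = pd.DataFrame({"patient_id": patients})
    for g in germ_genes:
        carriers = set(retained.loc[retained["gene"] == g, "patient_id"])
        cohort[f"g_{g}"] = patients.isin(carriers).to_numpy()
    for s in som_genes:
        mut = set(somatic.loc[(somatic["gene"] == s) & somatic["functional"], "sample"])
        cohort[f"s_{s}"] = patients.isin(mut).to_numpy()
    io_formats.write_table(cohort, out / "cohort_flags.tsv")

    if config.run_interactions and germ_genes and som_genes:
        pairs = association.pairwise_interactions(cohort, germ_genes, som_genes,
                                                  alpha=config.fdr_threshold)
        io_formats.write_table(pairs, out / "interactions.tsv")
        manifest["stages"]["interactions"] = {
            "in": len(germ_genes) * len(som_genes), "out": int(len(pairs)), "rejected": 0}
    else:
        manifest["stages"]["interactions"] = {"skipped": True}

    if config.run_case_control and config.control_counts:
        ctrl = io_formats.read_control_counts(config.control_counts)
        case_counts = {g: int(cohort[f"g_{g}"].sum()) for g in germ_genes}
        enr = association.case_control_enrichment(
            case_counts, {r.gene: int(r.carriers) for r in ctrl.itertuples()},
            n_case=len(cohort), n_control=int(ctrl["n"].iloc[0]),
            fdr_threshold=config.fdr_threshold)
        io_formats.write_table(enr, out / "enrichment.tsv")
        manifest["stages"]["case_control"] = {"in": int(len(enr)), "out": int(len(enr)),
                                              "rejected": 0,
                                              "significant": int(enr["significant"].sum())}
    else:
        manifest["stages"]["case_control"] = {"skipped": True}

    # --- risk modelling ----------------------------------------------------
    if config.run_risk:
        carrier_flag = (cohort[[c for c in cohort.columns if c.startswith("g_")]]
                        .any(axis=1).astype(int)
                        if germ_genes else pd.Series(0, index=cohort.index))
        data = clinical.copy()
        data["carrier"] = carrier_flag.to_numpy()
        covars = riskmodel.bcdg_model().covariates
        completed = riskmodel.impute_chained(data, seed=config.seed, columns=covars).data
        if completed["carrier"].nunique() < 2 or len(completed) < 10:
            manifest["stages"]["risk"] = {"skipped": True,
                                          "reason": "outcome constant or cohort too small"}
        else:
            train, valid = riskmodel.split_train_validation(completed, 0.7, config.seed)
            model = riskmodel.LogisticRiskModel.from_dataframe(train, "carrier", covars)
            res = model.fit()
            report = res.validate(valid[covars], valid["carrier"])
            res.spec.to_json(out / "risk_model.json")
            scored = pd.DataFrame({
                "patient_id": completed["patient_id"],
                "score": res.spec.linear_predictor(completed[covars]),
                "probability": res.spec.predict_proba(completed[covars])})
            io_formats.write_table(scored, out / "risk_scores.tsv")
            with open(out / "validation.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest["stages"]["risk"] = {"in": int(len(completed)),
                                          "out": int(len(scored)), "rejected": 0,
                                          "auc": round(report.auc, 4)}
    else:
        manifest["stages"]["risk"] = {"skipped": True}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_simulated_inputs(config: SimulationConfig, out_dir) -> dict:
    """Generate a synthetic cohort and write all pipeline input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(config)
    io_formats.write_germline_table(sim.germline, out / "germline.tsv")
    io_formats.write_somatic(sim.somatic, out / "somatic.tsv")
    io_formats.write_segments(sim.segments, out / "segments.tsv")
    io_formats.write_table(sim.purity, out / "purity.tsv",
                           columns=["sample", "purity", "ploidy"])
    io_formats.write_clinical(sim.clinical, out / "clinical.tsv")
    # control counts: a synthetic control population at half the case frequency
    genes = sorted(config.germline_frequencies)
    n_ctrl = 10000
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[-1])
    ctrl = pd.DataFrame({
        "gene": genes,
        "carriers": [int(rng.binomial(n_ctrl, config.germline_frequencies[g] / 4))
                     for g in genes],
        "n": n_ctrl})
    io_formats.write_table(ctrl, out / "control_counts.tsv")
    for name, df in sim.truth.items():
        if isinstance(df, pd.DataFrame) and not df.empty:
            io_formats.write_table(df, out / f"truth_{name}.tsv")
    return {"n_patients": config.n_patients, "out_dir": str(out)}
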