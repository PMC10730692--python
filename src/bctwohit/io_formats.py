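"""Readers and writers for the tabular formats consumed by the toolkit.

All genomic coordinates are 1-based inclusive (SEG convention).  Every reader
validates its input and raises :class:`ValidationError` naming the offending
row; no row is ever dropped silently.  Writers emit tab-separated text with a
fixed column order so that ``write(read(x))`` round-trips canonical files
byte-for-byte.
"""

from __future__ import annotations

import io
import os
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SEGMENT_COLUMNS",
    "SOMATIC_COLUMNS",
    "CLINICAL_COLUMNS",
    "GERMLINE_COLUMNS",
    "FUNCTIONAL_CLASSES",
    "VARIANT_CLASSES",
    "read_segments",
    "write_segments",
    "read_somatic_maf",
    "write_somatic",
    "read_clinical",
    "write_clinical",
    "read_germline_table",
    "write_germline_table",
    "read_germline_vcf",
    "read_control_counts",
    "read_purity",
    "write_table",
]


class ValidationError(ValueError):
    """Raised when an input file violates a format invariant."""


SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "tcn", "lcn"]
SOMATIC_COLUMNS = ["sample", "gene", "variant_class", "chrom", "pos", "ref", "alt", "functional"]
CLINICAL_COLUMNS = [
    "patient_id", "age", "grade", "T", "N", "M", "ER", "PR", "HER2", "Ki67",
    "contralateral", "FHBC", "FHOC", "other_cancer_history", "subtype",
]
GERMLINE_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "depth", "alt_ad",
    "vaf", "genotype_homozygous", "annotation_a", "annotation_b", "clinvar",
    "tumor_depth", "tumor_alt",
]

#: Closed somatic variant-classification vocabulary.
VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "silent", "other")
#: Classes that count as functional (second-hit capable) somatic mutations.
FUNCTIONAL_CLASSES = ("missense", "nonsense", "frameshift", "splice")

# MAF-dialect Variant_Classification values mapped onto the closed vocabulary;
# anything not listed maps to "other".
_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "nonstop_mutation": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
    "splice_site": "splice",
    "splice_region": "splice",
    "splice": "splice",
    "silent": "silent",
    "synonymous": "silent",
}

_BINARY_CLINICAL = ["M", "ER", "PR", "HER2", "contralateral", "FHBC", "FHOC", "other_cancer_history"]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")


def read_segments(path) -> pd.DataFrame:
    """Read allele-specific copy-number segments from a SEG-style TSV.

    Expects columns ``sample, chrom, start, end, tcn, lcn`` (1-based inclusive
    coordinates).  Validates ``start <= end``, ``lcn <= tcn``, non-negative
    integer copy numbers, and per-(sample, chrom) non-overlap.  Rows are
    returned sorted by (sample, chrom, start).
    """
    df = _read_tsv(path)
    _require_columns(df, SEGMENT_COLUMNS, path)
    df = df[SEGMENT_COLUMNS].copy()
    for col in ("start", "end", "tcn", "lcn"):
        try:
            df[col] = df[col].astype(np.int64)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer value in column {col!r}: {exc}") from None
    return validate_segments(df, name=str(path))


def validate_segments(df: pd.DataFrame, name: str = "segments") -> pd.DataFrame:
    """Validate an in-memory segment table; returns it sorted."""
    for i, row in enumerate(df.itertuples(index=False)):
        if row.start > row.end:
            raise ValidationError(f"{name}: row {i}: start > end ({row.start} > {row.end})")
        if row.lcn > row.tcn:
            raise ValidationError(f"{name}: row {i}: LCN > TCN ({row.lcn} > {row.tcn})")
        if row.lcn < 0:
            raise ValidationError(f"{name}: row {i}: negative LCN")
    df = df.sort_values(["sample", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        overlap = starts[1:] <= ends[:-1]
        if overlap.any():
            j = int(np.flatnonzero(overlap)[0])
            raise ValidationError(
                f"{name}: overlapping segments on {sample}/{chrom} "
                f"(segment ending {ends[j]} overlaps segment starting {starts[j + 1]})"
            )
    return df


def read_somatic_maf(path) -> pd.DataFrame:
    """Read a MAF-dialect somatic mutation table.

    Requires at least ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
    ``Variant_Classification``.  The classification is mapped onto the closed
    vocabulary (unknown classes become ``other``).  If the file carries no
    explicit ``functional`` column, a mutation is flagged functional when its
    class is missense, nonsense, frameshift or splice.
    """
    df = _read_tsv(path)
    if set(SOMATIC_COLUMNS).issubset(df.columns):  # canonical dialect round-trips
        out = df[SOMATIC_COLUMNS].copy()
        out["pos"] = out["pos"].astype(np.int64)
        out["functional"] = out["functional"].str.lower().isin(["true", "1", "yes"])
        bad = ~out["variant_class"].isin(VARIANT_CLASSES)
        if bad.any():
            raise ValidationError(f"{path}: unknown variant class {out.loc[bad, 'variant_class'].iloc[0]!r}")
        return out
    _require_columns(df, ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"], path)
    out = pd.DataFrame({
        "sample": df["Tumor_Sample_Barcode"].str.strip(),
        "gene": df["Hugo_Symbol"].str.strip(),
        "variant_class": df["Variant_Classification"].str.strip().str.lower().map(
            lambda v: _MAF_CLASS_MAP.get(v, "other")
        ),
        "chrom": df.get("Chromosome", pd.Series([""] * len(df))).astype(str),
        "pos": pd.to_numeric(df.get("Start_Position", pd.Series([0] * len(df))), errors="coerce").fillna(0).astype(np.int64),
        "ref": df.get("Reference_Allele", pd.Series([""] * len(df))).astype(str),
        "alt": df.get("Tumor_Seq_Allele2", pd.Series([""] * len(df))).astype(str),
    })
    if "functional" in df.columns:
        out["functional"] = df["functional"].astype(str).str.lower().isin(["true", "1", "yes"])
    else:
        out["functional"] = out["variant_class"].isin(FUNCTIONAL_CLASSES)
    return out[SOMATIC_COLUMNS]


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical covariate table; blank cells become NaN (missing).

    Enforces Ki67 within [0, 100] and binary fields within {0, 1, missing}.
    """
    df = _read_tsv(path)
    _require_columns(df, ["patient_id"], path)
    out = pd.DataFrame({"patient_id": df["patient_id"].str.strip()})
    for col in CLINICAL_COLUMNS[1:]:
        if col == "subtype":
            vals = df.get(col, pd.Series([""] * len(df))).astype(str).str.strip()
            out[col] = vals.replace("", np.nan)
            continue
        raw = df.get(col, pd.Series([""] * len(df))).astype(str).str.strip()
        out[col] = pd.to_numeric(raw.mask(raw == ""), errors="raise")
    bad = out["Ki67"].dropna()
    if ((bad < 0) | (bad > 100)).any():
        i = out.index[(out["Ki67"] < 0) | (out["Ki67"] > 100)][0]
        raise ValidationError(f"{path}: row {i}: Ki67 outside [0, 100] ({out.loc[i, 'Ki67']})")
    for col in _BINARY_CLINICAL:
        vals = out[col].dropna()
        if (~vals.isin([0, 1])).any():
            raise ValidationError(f"{path}: column {col!r} has values outside {{0, 1, missing}}")
    return out


def read_germline_table(path) -> pd.DataFrame:
    """Read the VCF-like germline variant TSV used for interchange.

    One row per germline call: sequencing metrics (depth, alt AD, VAF),
    genotype homozygosity flag and the two pathogenicity annotations plus an
    optional ClinVar label.
    """
    df = _read_tsv(path)
    _require_columns(df, ["patient_id", "gene", "depth", "alt_ad", "vaf"], path)
    out = pd.DataFrame({
        "patient_id": df["patient_id"].str.strip(),
        "gene": df["gene"].str.strip(),
        "chrom": df.get("chrom", pd.Series([""] * len(df))).astype(str),
        "pos": pd.to_numeric(df.get("pos", pd.Series([0] * len(df))), errors="coerce").fillna(0).astype(np.int64),
        "ref": df.get("ref", pd.Series([""] * len(df))).astype(str),
        "alt": df.get("alt", pd.Series([""] * len(df))).astype(str),
        "depth": pd.to_numeric(df["depth"].mask(df["depth"] == ""), errors="coerce"),
        "alt_ad": pd.to_numeric(df["alt_ad"].mask(df["alt_ad"] == ""), errors="coerce"),
        "vaf": pd.to_numeric(df["vaf"].mask(df["vaf"] == ""), errors="coerce"),
        "genotype_homozygous": df.get("genotype_homozygous", pd.Series(["False"] * len(df)))
        .astype(str).str.lower().isin(["true", "1", "yes"]),
        "annotation_a": df.get("annotation_a", pd.Series([""] * len(df))).astype(str).str.strip(),
        "annotation_b": df.get("annotation_b", pd.Series([""] * len(df))).astype(str).str.strip(),
        "clinvar": df.get("clinvar", pd.Series([""] * len(df))).astype(str).str.strip(),
        "tumor_depth": pd.to_numeric(
            df.get("tumor_depth", pd.Series([""] * len(df))).mask(lambda s: s == ""),
            errors="coerce"),
        "tumor_alt": pd.to_numeric(
            df.get("tumor_alt", pd.Series([""] * len(df))).mask(lambda s: s == ""),
            errors="coerce"),
    })
    ok = out["vaf"].dropna()
    if ((ok < 0) | (ok > 1)).any():
        raise ValidationError(f"{path}: VAF outside [0, 1]")
    both = out.dropna(subset=["depth", "alt_ad"])
    if (both["alt_ad"] > both["depth"]).any():
        raise ValidationError(f"{path}: alt AD exceeds depth")
    return out[GERMLINE_COLUMNS]


def read_germline_vcf(path) -> pd.DataFrame:
    """Minimal VCF 4.x reader for single-sample germline calls (via cyvcf2).

    Extracts CHROM/POS/REF/ALT, DP and AD from the first sample, computes
    VAF = alt_AD / DP, and flags homozygous genotypes.  Pathogenicity labels
    are taken from the INFO keys ``ANNA``, ``ANNB`` and ``CLNSIG`` when
    present (they arrive as annotations, never computed here).
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    if len(vcf.samples) != 1:
        raise ValidationError(f"{path}: expected a single-sample VCF, found {len(vcf.samples)} samples")
    patient = vcf.samples[0]
    rows = []
    for rec in vcf:
        depth = int(rec.format("DP")[0][0]) if rec.format("DP") is not None else np.nan
        ad = rec.format("AD")
        alt_ad = int(ad[0][1]) if ad is not None and ad.shape[1] > 1 else np.nan
        vaf = alt_ad / depth if depth and not np.isnan(alt_ad) else np.nan
        gt = rec.genotypes[0][:-1]
        rows.append({
            "patient_id": patient,
            "gene": rec.INFO.get("GENE", ""),
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else "",
            "depth": depth,
            "alt_ad": alt_ad,
            "vaf": vaf,
            "genotype_homozygous": len(set(gt)) == 1 and gt[0] == 1,
            "annotation_a": rec.INFO.get("ANNA", ""),
            "annotation_b": rec.INFO.get("ANNB", ""),
            "clinvar": rec.INFO.get("CLNSIG", ""),
        })
    vcf.close()
    return pd.DataFrame(rows, columns=GERMLINE_COLUMNS)


def read_control_counts(path) -> pd.DataFrame:
    """Read per-gene control-population carrier counts (gene, carriers, n)."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "carriers", "n"], path)
    out = pd.DataFrame({
        "gene": df["gene"].str.strip(),
        "carriers": df["carriers"].astype(np.int64),
        "n": df["n"].astype(np.int64),
    })
    if (out["carriers"] > out["n"]).any():
        raise ValidationError(f"{path}: carrier count exceeds population size")
    return out


def read_purity(path) -> pd.DataFrame:
    """Read per-sample tumor purity and ploidy (sample, purity, ploidy)."""
    df = _read_tsv(path)
    _require_columns(df, ["sample", "purity", "ploidy"], path)
    out = pd.DataFrame({
        "sample": df["sample"].str.strip(),
        "purity": pd.to_numeric(df["purity"].mask(df["purity"] == ""), errors="coerce"),
        "ploidy": pd.to_numeric(df["ploidy"].mask(df["ploidy"] == ""), errors="coerce"),
    })
    ok = out["purity"].dropna()
    if ((ok <= 0) | (ok > 1)).any():
        raise ValidationError(f"{path}: purity outside (0, 1]")
    return out


def write_table(df: pd.DataFrame, path, columns=None, header_comment: str | None = None) -> None:
    """Write a TSV with fixed column order and stable float formatting."""
    if columns is not None:
        df = df[list(columns)]
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g", na_rep="")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_segments(df: pd.DataFrame, path, **kw) -> None:
    write_table(df, path, columns=SEGMENT_COLUMNS, **kw)


def write_somatic(df: pd.DataFrame, path, **kw) -> None:
    write_table(df, path, columns=SOMATIC_COLUMNS, **kw)


def write_clinical(df: pd.DataFrame, path, **kw) -> None:
    write_table(df, path, columns=CLINICAL_COLUMNS, **kw)


def write_germline_table(df: pd.DataFrame, path, **kw) -> None:
    write_table(df, path, columns=GERMLINE_COLUMNS, **kw)
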