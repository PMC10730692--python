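"""Three-component homologous-recombination-deficiency (HRD) scoring.

The score sums three counts over a tumor's allele-specific copy-number
segments:

* **NtAI** -- allelic-imbalance segments (TCN != 2*LCN) that reach a
  telomere, do not cross the centromere and exceed 11 Mb;
* **LOH**  -- segments with LCN = 0 and TCN >= 1 longer than 15 Mb but
  shorter than the whole chromosome;
* **LSTm** -- large-scale state transitions (breakpoints between >= 10 Mb
  segments after filtering < 3 Mb segments, counted per chromosome arm)
  with the ploidy correction LSTm = LST - 15.5 * ploidy.

Thresholds follow the literature-standard definitions and are exposed as
keyword arguments, not hard-coded.  Adjacent segments with identical
(TCN, LCN) are merged canonically before any counting, so results are
invariant under splitting a segment in two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "HRDResult",
    "toy_genome",
    "merge_segments",
    "ntai",
    "loh_score",
    "lst_raw",
    "lstm",
    "hrd_score",
    "LSTM_PLOIDY_COEF",
]

#: Ploidy coefficient of the modified LST score.
LSTM_PLOIDY_COEF = 15.5

MB = 1_000_000


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and centromere intervals (1-based inclusive)."""

    chrom_length: dict
    centromere: dict  # chrom -> (start, end), strictly inside the chromosome

    def __post_init__(self):
        for chrom, (cs, ce) in self.centromere.items():
            if not 1 < cs <= ce < self.chrom_length[chrom]:
                raise ValueError(f"centromere of {chrom} not strictly inside chromosome")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GenomeBuild":
        """Build from a table with chrom, length, centromere_start, centromere_end."""
        return cls(
            chrom_length={str(r.chrom): int(r.length) for r in df.itertuples()},
            centromere={str(r.chrom): (int(r.centromere_start), int(r.centromere_end))
                        for r in df.itertuples()},
        )


def toy_genome(n_chrom: int = 22, length: int = 130 * MB,
               centromere=(60 * MB, 65 * MB)) -> GenomeBuild:
    """Uniform synthetic genome: ``n_chrom`` chromosomes named chr1..chrN."""
    chroms = [f"chr{i}" for i in range(1, n_chrom + 1)]
    return GenomeBuild({c: length for c in chroms}, {c: centromere for c in chroms})


@dataclass(frozen=True)
class HRDResult:
    """Per-sample HRD components; HRD_sum = NtAI + LOH + LSTm."""

    ntai: int
    loh: int
    lst: int
    lstm: float
    hrd_sum: float
    ploidy: float


def _seg_len(df: pd.DataFrame) -> np.ndarray:
    return (df["end"] - df["start"] + 1).to_numpy()


def merge_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Canonical form: sorted, with adjacent identical (TCN, LCN) runs merged.

    Segments are merged whenever consecutive rows on a chromosome share the
    same copy state, regardless of gaps (panel segmentations leave uncovered
    baits between segments of one state).
    """
    segments = segments.sort_values(["chrom", "start"], kind="mergesort")
    rows = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and (row.tcn, row.lcn) == (cur["tcn"], cur["lcn"]):
                cur["end"] = row.end
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "tcn": row.tcn, "lcn": row.lcn}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tcn", "lcn"])


def ntai(segments: pd.DataFrame, genome: GenomeBuild,
         min_size: int = 11 * MB) -> int:
    """Telomeric allelic-imbalance count."""
    seg = merge_segments(segments)
    count = 0
    for row in seg.itertuples(index=False):
        chrom = str(row.chrom)
        if row.tcn == 2 * row.lcn:  # balanced
            continue
        length = row.end - row.start + 1
        if length <= min_size:
            continue
        telomeric = row.start == 1 or row.end == genome.chrom_length[chrom]
        if not telomeric:
            continue
        cs, ce = genome.centromere[chrom]
        crosses = row.start < cs and row.end > ce
        if crosses:
            continue
        count += 1
    return count


def loh_score(segments: pd.DataFrame, genome: GenomeBuild,
              min_size: int = 15 * MB,
              exclude_whole_chromosome: bool = True) -> int:
    """Loss-of-heterozygosity count (LCN = 0 segments > 15 Mb, sub-chromosomal)."""
    seg = merge_segments(segments)
    count = 0
    for row in seg.itertuples(index=False):
        if not (row.lcn == 0 and row.tcn >= 1):
            continue
        length = row.end - row.start + 1
        if length <= min_size:
            continue
        if exclude_whole_chromosome:
            chrom = str(row.chrom)
            if row.start == 1 and row.end == genome.chrom_length[chrom]:
                continue
        count += 1
    return count


def _arm_intervals(genome: GenomeBuild, chrom: str) -> list[tuple[int, int]]:
    cs, ce = genome.centromere[chrom]
    return [(1, cs - 1), (ce + 1, genome.chrom_length[chrom])]


def lst_raw(segments: pd.DataFrame, genome: GenomeBuild,
            min_flank: int = 10 * MB, smooth_below: int = 3 * MB) -> int:
    """Large-scale state transition count.

    Per chromosome arm: clip segments to the arm, discard segments shorter
    than ``smooth_below``, re-merge identical neighbours across the gaps
    left by discarded segments, then count breakpoints whose two flanking
    segments are both at least ``min_flank`` long and differ in (TCN, LCN).
    """
    seg = merge_segments(segments)
    count = 0
    for chrom, grp in seg.groupby("chrom", sort=False):
        for a_start, a_end in _arm_intervals(genome, str(chrom)):
            clipped = grp.copy()
            clipped["start"] = clipped["start"].clip(lower=a_start)
            clipped["end"] = clipped["end"].clip(upper=a_end)
            clipped = clipped[clipped["start"] <= clipped["end"]]
            clipped = clipped[_seg_len(clipped) >= smooth_below]
            if len(clipped) < 2:
                continue
            clipped = merge_segments(clipped)
            lens = _seg_len(clipped)
            states = list(zip(clipped["tcn"], clipped["lcn"]))
            for i in range(len(clipped) - 1):
                if states[i] != states[i + 1] and lens[i] >= min_flank and lens[i + 1] >= min_flank:
                    count += 1
    return count


def lstm(lst: int, ploidy: float) -> float:
    """Ploidy-corrected LST: LST - 15.5 * ploidy."""
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    return lst - LSTM_PLOIDY_COEF * ploidy


def hrd_score(segments: pd.DataFrame, ploidy: float, genome: GenomeBuild,
              **thresholds) -> HRDResult:
    """Full HRD result for one sample's segments."""
    ntai_kw = {k[5:]: v for k, v in thresholds.items() if k.startswith("ntai_")}
    loh_kw = {k[4:]: v for k, v in thresholds.items() if k.startswith("loh_")}
    lst_kw = {k[4:]: v for k, v in thresholds.items() if k.startswith("lst_")}
    n = ntai(segments, genome, **ntai_kw)
    l = loh_score(segments, genome, **loh_kw)
    t = lst_raw(segments, genome, **lst_kw)
    tm = lstm(t, ploidy)
    return HRDResult(ntai=n, loh=l, lst=t, lstm=tm, hrd_sum=n + l + tm, ploidy=ploidy)


def hrd_table(segments: pd.DataFrame, purity_ploidy: pd.DataFrame,
              genome: GenomeBuild, **thresholds) -> pd.DataFrame:
    """Per-sample HRD table from a multi-sample segment file."""
    ploidy_map = dict(zip(purity_ploidy["sample"], purity_ploidy["ploidy"]))
    rows = []
    for sample, grp in segments.groupby("sample", sort=True):
        res = hrd_score(grp, float(ploidy_map[sample]), genome, **thresholds)
        rows.append({"sample": sample, "ntai": res.ntai, "loh": res.loh,
                     "lst": res.lst, "lstm": res.lstm, "hrd_sum": res.hrd_sum,
                     "ploidy": res.ploidy})
    return pd.DataFrame(rows, columns=["sample", "ntai", "loh", "lst", "lstm",
                                       "hrd_sum", "ploidy"])
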