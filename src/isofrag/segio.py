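"""Reading, writing and interrogating allele-specific copy-number inputs.

Segment tables are tab-delimited with columns ``sample``, ``chrom``,
``start``, ``end``, ``nMajor``, ``nMinor``; coordinates on disk are 1-based
inclusive (the dominant segment-file dialect) and are normalised to 0-based
half-open internally.  Centromere annotations come either from a UCSC
"centromeres" table export or plain BED3; multiple rows per chromosome are
merged into a single span whose midpoint demarcates the p and q arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "nMajor", "nMinor"]

#: Chromosomes excluded from isochromosome calling by default: the five
#: acrocentrics (their short-arm LOH status cannot be established from
#: array copy number) and Y.
DEFAULT_EXCLUDED_CHROMS = frozenset(
    {"chr13", "chr14", "chr15", "chr21", "chr22", "chrY", "13", "14", "15", "21", "22", "Y"}
)

LOH = "LOH"
HETEROZYGOUS = "heterozygous"
NO_DATA = "no_data"

DELETERIOUS_CONSEQUENCES = frozenset({"stop_gain", "frameshift"})


class SegmentTableError(ValueError):
    """Raised when a segment table violates its invariants."""


@dataclass(frozen=True)
class SegmentRecord:
    """One allele-specific copy-number interval of one sample.

    Coordinates are internal convention: 0-based half-open.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SegmentTableError(f"empty or inverted interval: {self}")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise SegmentTableError(f"copy numbers must satisfy major >= minor >= 0: {self}")


@dataclass(frozen=True)
class CentromereSpan:
    chrom: str
    cen_start: int
    cen_end: int

    @property
    def midpoint(self) -> int:
        return (self.cen_start + self.cen_end) // 2


@dataclass
class CentromereMap:
    """Merged centromere span per chromosome.

    The merged span is [min(starts), max(ends)] over all centromeric rows of
    a chromosome, so the "smallest/largest coordinate" and "centre of the
    merged region" constructions coincide and are served by one map.
    """

    spans: dict[str, CentromereSpan] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.spans

    def __getitem__(self, chrom: str) -> CentromereSpan:
        return self.spans[chrom]

    def midpoint(self, chrom: str) -> int:
        return self.spans[chrom].midpoint

    def chromosomes(self) -> list[str]:
        return sorted(self.spans)


def _check_no_overlap(df: pd.DataFrame) -> None:
    bad: list[str] = []
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            idx = g.index.to_numpy()[1:][overlap]
            bad.append(f"{sample}/{chrom} rows {list(idx)}")
    if bad:
        raise SegmentTableError("overlapping segments: " + "; ".join(bad))


def normalize_segments(
    df: pd.DataFrame,
    allele_order: Literal["ordered", "unordered"] = "ordered",
    coords: Literal["1-based", "0-based"] = "1-based",
) -> pd.DataFrame:
    """Validate a raw segment table and normalise to the internal convention.

    ``allele_order="unordered"`` swaps the two allele columns where needed;
    with ``"ordered"`` a row with nMajor < nMinor is rejected.
    """
    df = df.loc[:, SEGMENT_COLUMNS].copy()
    for col in ("start", "end", "nMajor", "nMinor"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    if coords == "1-based":
        df["start"] = df["start"] - 1
    if (df["nMajor"] < 0).any() or (df["nMinor"] < 0).any():
        raise SegmentTableError("negative copy numbers")
    swapped = df["nMajor"] < df["nMinor"]
    if swapped.any():
        if allele_order == "unordered":
            maj = df["nMajor"].where(~swapped, df["nMinor"])
            mino = df["nMinor"].where(~swapped, df["nMajor"])
            df["nMajor"], df["nMinor"] = maj, mino
        else:
            raise SegmentTableError(
                f"nMajor < nMinor in rows {list(df.index[swapped])} (ordered dialect)"
            )
    if (df["start"] >= df["end"]).any():
        bad = list(df.index[df["start"] >= df["end"]])
        raise SegmentTableError(f"empty or inverted intervals in rows {bad}")
    _check_no_overlap(df)
    return df.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)


def read_segments(
    path, allele_order: Literal["ordered", "unordered"] = "ordered"
) -> pd.DataFrame:
    """Read a tab-delimited segment table (1-based inclusive coordinates)."""
    raw = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise SegmentTableError(f"missing columns: {missing}")
    return normalize_segments(raw, allele_order=allele_order)


def write_segments(df: pd.DataFrame, path) -> None:
    """Write an internal table back to the 1-based inclusive disk dialect."""
    out = df.loc[:, SEGMENT_COLUMNS].copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def iter_records(df: pd.DataFrame) -> Iterable[SegmentRecord]:
    for row in df.itertuples(index=False):
        yield SegmentRecord(row.sample, row.chrom, row.start, row.end, row.nMajor, row.nMinor)


def read_centromeres(path) -> CentromereMap:
    """Load centromere annotations from a UCSC table export or BED3 file."""
    first = open(path).readline()
    if "chromStart" in first:  # UCSC table browser export
        tab = pd.read_csv(path, sep="\t")
        tab = tab.rename(columns={"chromStart": "start", "chromEnd": "end"})
        if "#chrom" in tab.columns:
            tab = tab.rename(columns={"#chrom": "chrom"})
    else:
        tab = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
            comment="#",
        )
    return centromere_map_from_rows(
        tab["chrom"].astype(str), tab["start"].astype(int), tab["end"].astype(int)
    )


def centromere_map_from_rows(chroms, starts, ends) -> CentromereMap:
    spans: dict[str, CentromereSpan] = {}
    frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    for chrom, grp in frame.groupby("chrom", sort=False):
        spans[str(chrom)] = CentromereSpan(str(chrom), int(grp["start"].min()), int(grp["end"].max()))
    return CentromereMap(spans)


def read_gene_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED4 (name column required); 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], comment="#",
        dtype={0: str, 3: str},
    )
    return df


def read_mutations(path) -> pd.DataFrame:
    """Read a mutation table: sample, gene, consequence, t_alt_freq."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "consequence": str})
    needed = ["sample", "gene", "consequence", "t_alt_freq"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    af = df["t_alt_freq"].astype(float)
    if ((af < 0) | (af > 1)).any():
        raise ValueError("allele frequencies must be in [0, 1]")
    return df


def filter_deleterious_mutations(
    mutations: pd.DataFrame, gene: str, min_af: float = 0.5
) -> pd.DataFrame:
    """Keep unambiguous deleterious calls for one gene.

    A record survives iff it hits ``gene``, its consequence is a stop-codon
    gain or frameshift, and its tumour allele frequency is >= ``min_af``
    (default 0.5, i.e. clonal in a diploid region).
    """
    if not 0.0 <= min_af <= 1.0:
        raise ValueError("min_af must be in [0, 1]")
    keep = (
        (mutations["gene"] == gene)
        & mutations["consequence"].isin(DELETERIOUS_CONSEQUENCES)
        & (mutations["t_alt_freq"].astype(float) >= min_af)
    )
    return mutations.loc[keep]


def locus_loh_status(sample_segments: pd.DataFrame, chrom: str, start: int, end: int) -> str:
    """LOH status of one locus for one sample.

    LOH means the length-weighted modal minor copy number over the covered
    portion of ``[start, end)`` is zero; ties between zero and non-zero
    minor copy break toward heterozygous (conservative for association
    testing).  Returns ``no_data`` when no segment overlaps the locus.
    """
    segs = sample_segments
    on = segs[(segs["chrom"] == chrom) & (segs["end"] > start) & (segs["start"] < end)]
    if on.empty:
        return NO_DATA
    ov = np.minimum(on["end"].to_numpy(), end) - np.maximum(on["start"].to_numpy(), start)
    minor = on["nMinor"].to_numpy()
    zero_bp = int(ov[minor == 0].sum())
    nonzero_bp = int(ov[minor > 0].sum())
    return LOH if zero_bp > nonzero_bp else HETEROZYGOUS


def coalesce_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Merge touching equal-copy segments per sample/chromosome.

    Makes every downstream quantity invariant to subdividing a segment into
    adjacent equal-copy pieces, and implements the rule that equal-copy
    fragments immediately flanking the centromere act as a single fragment.
    """
    parts: list[pd.DataFrame] = []
    for _, grp in df.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        maj = g["nMajor"].to_numpy()
        mino = g["nMinor"].to_numpy()
        new_run = np.ones(len(g), dtype=bool)
        if len(g) > 1:
            same = (starts[1:] == ends[:-1]) & (maj[1:] == maj[:-1]) & (mino[1:] == mino[:-1])
            new_run[1:] = ~same
        run_id = np.cumsum(new_run)
        merged = g.assign(_run=run_id).groupby("_run", sort=True).agg(
            sample=("sample", "first"), chrom=("chrom", "first"),
            start=("start", "min"), end=("end", "max"),
            nMajor=("nMajor", "first"), nMinor=("nMinor", "first"),
        )
        parts.append(merged.reset_index(drop=True))
    if not parts:
        return df.copy()
    return pd.concat(parts, ignore_index=True)[SEGMENT_COLUMNS]
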