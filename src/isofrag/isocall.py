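"""The five-condition isochromosome caller.

An isochromosome duplicates one chromosome arm in mirror image while the
complementary arm is lost, so the allele-specific copy-number footprint is
an arm with loss of heterozygosity (modal minor copy = 0) opposite an arm
whose duplicated allele carries at least two copies.  Calling operates on
length-weighted modal copy numbers per arm and is invariant to how the
segmentation happens to split equal-copy runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .segio import (
    DEFAULT_EXCLUDED_CHROMS,
    CentromereMap,
    coalesce_segments,
)

log = logging.getLogger(__name__)

MONOCENTRIC = "monocentric"
DICENTRIC = "dicentric"


@dataclass(frozen=True)
class ArmMode:
    """Length-weighted modal copy numbers of one chromosome arm.

    Each track (major, minor, total) is tallied independently, so
    ``modal_total`` need not equal ``modal_major + modal_minor`` on arms
    with mixed segments.
    """

    chrom: str
    arm: str  # "p" or "q"
    modal_major: int
    modal_minor: int
    modal_total: int
    covered_bp: int


@dataclass
class IsoCall:
    sample_id: str
    chrom: str
    loh_arm: str
    retained_arm: str
    iso_allele: str  # "major" or "minor" allele of the retained arm
    iso_allele_cn: int
    centricity: Optional[str] = None
    fusion_site: Optional[int] = None
    fusion_distance: Optional[int] = None
    n_het_fragments: Optional[int] = None
    data_gap: bool = False


def _weighted_mode(values: np.ndarray, weights: np.ndarray) -> int:
    """Value with the largest total weight; ties break to the smallest value."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    uniq, idx = np.unique(v, return_index=True)
    sums = np.add.reduceat(w, idx)
    return int(uniq[np.argmax(sums)])


def _clip_to_arm(segs: pd.DataFrame, lo: int, hi: int) -> pd.DataFrame:
    on = segs[(segs["end"] > lo) & (segs["start"] < hi)].copy()
    if on.empty:
        return on
    on["start"] = on["start"].clip(lower=lo)
    on["end"] = on["end"].clip(upper=hi)
    return on


def modal_arm_copy_numbers(
    chrom_segments: pd.DataFrame, chrom: str, centromeres: CentromereMap
) -> tuple[Optional[ArmMode], Optional[ArmMode]]:
    """Length-weighted modal (major, minor, total) per arm of one chromosome.

    The p arm is everything left of the centromere midpoint, the q arm
    everything right of it.  Returns ``None`` for an arm with zero coverage.
    """
    mid = centromeres.midpoint(chrom)
    out: list[Optional[ArmMode]] = []
    for arm, lo, hi in (("p", 0, mid), ("q", mid, np.iinfo(np.int64).max)):
        on = _clip_to_arm(chrom_segments, lo, hi)
        if on.empty:
            out.append(None)
            continue
        w = (on["end"] - on["start"]).to_numpy()
        maj = on["nMajor"].to_numpy()
        mino = on["nMinor"].to_numpy()
        out.append(
            ArmMode(
                chrom=chrom,
                arm=arm,
                modal_major=_weighted_mode(maj, w),
                modal_minor=_weighted_mode(mino, w),
                modal_total=_weighted_mode(maj + mino, w),
                covered_bp=int(w.sum()),
            )
        )
    return out[0], out[1]


def telomeric_minor_cn(chrom_segments: pd.DataFrame, chrom: str, arm: str, midpoint: int) -> Optional[int]:
    """Minor copy number of the outermost covered segment of one arm."""
    if arm == "p":
        on = chrom_segments[chrom_segments["start"] < midpoint]
        if on.empty:
            return None
        return int(on.loc[on["start"].idxmin(), "nMinor"])
    on = chrom_segments[chrom_segments["end"] > midpoint]
    if on.empty:
        return None
    return int(on.loc[on["end"].idxmax(), "nMinor"])


def call_isochromosome(
    p_mode: ArmMode,
    q_mode: ArmMode,
    telomeric_minor_p: int,
    telomeric_minor_q: int,
    sample_id: str = "",
) -> Optional[IsoCall]:
    """Apply the five calling conditions to one chromosome of one sample.

    1. one arm has LOH (modal minor copy number 0);
    2. the other arm is heterozygous (modal minor > 0);
    3. the LOH arm's modal major is at least two less than the heterozygous
       arm's modal *total*;
    4. whichever allele of the heterozygous arm is closer (ties to major) to
       the LOH arm's modal major is the duplicated isochromosome allele and
       must carry >= 2 copies;
    5. the telomeric end of the LOH arm has minor copy number 0 (guards
       against partial-arm LOH mechanisms that keep the telomere
       heterozygous).

    If both arms have modal minor 0, condition 2 is unsatisfiable and the
    chromosome is a no-call.
    """
    p_loh = p_mode.modal_minor == 0
    q_loh = q_mode.modal_minor == 0
    if p_loh == q_loh:  # neither or both: conditions 1+2 cannot hold
        return None
    if p_loh:
        loh, het = p_mode, q_mode
        tel_minor = telomeric_minor_p
    else:
        loh, het = q_mode, p_mode
        tel_minor = telomeric_minor_q
    if loh.modal_major > het.modal_total - 2:
        return None
    d_minor = abs(loh.modal_major - het.modal_minor)
    d_major = abs(loh.modal_major - het.modal_major)
    if d_minor <= d_major:
        iso_allele, iso_cn = "major", het.modal_major
    else:
        iso_allele, iso_cn = "minor", het.modal_minor
    if iso_cn < 2:
        return None
    if tel_minor != 0:
        return None
    return IsoCall(
        sample_id=sample_id,
        chrom=loh.chrom,
        loh_arm=loh.arm,
        retained_arm=het.arm,
        iso_allele=iso_allele,
        iso_allele_cn=int(iso_cn),
    )


def classify_centricity(
    call: IsoCall, chrom_segments: pd.DataFrame, centromeres: CentromereMap
) -> str:
    """Monocentric iff every covered bp of the LOH arm has minor copy 0.

    A monocentric isochromosome is fused at the centromere and loses the
    whole complementary arm; any heterozygous remnant inside the LOH arm
    implies an arm-internal fusion, i.e. a dicentric that bridged.
    """
    mid = centromeres.midpoint(call.chrom)
    lo, hi = (0, mid) if call.loh_arm == "p" else (mid, np.iinfo(np.int64).max)
    on = _clip_to_arm(chrom_segments, lo, hi)
    if on.empty:
        return MONOCENTRIC
    return DICENTRIC if (on["nMinor"] > 0).any() else MONOCENTRIC


def call_cohort(
    segments: pd.DataFrame,
    centromeres: CentromereMap,
    chromosomes: Optional[Iterable[str]] = None,
    excluded: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> list[IsoCall]:
    """Run the caller over every sample/chromosome of a cohort table.

    ``chromosomes`` restricts calling to an explicit set; otherwise every
    chromosome present in both the segments and the centromere map, minus
    the exclusion list, is screened.  Segments are coalesced first so calls
    do not depend on segmentation granularity.
    """
    segments = coalesce_segments(segments)
    excluded = set(excluded)
    calls: list[IsoCall] = []
    for (sample, chrom), grp in segments.groupby(["sample", "chrom"], sort=True):
        chrom = str(chrom)
        if chromosomes is not None and chrom not in set(chromosomes):
            continue
        if chromosomes is None and chrom in excluded:
            continue
        if chrom not in centromeres:
            log.warning("no centromere annotation for %s; skipped", chrom)
            continue
        mid = centromeres.midpoint(chrom)
        p_mode, q_mode = modal_arm_copy_numbers(grp, chrom, centromeres)
        if p_mode is None or q_mode is None:
            log.info("%s/%s: uncovered arm, skipped", sample, chrom)
            continue
        tel_p = telomeric_minor_cn(grp, chrom, "p", mid)
        tel_q = telomeric_minor_cn(grp, chrom, "q", mid)
        call = call_isochromosome(p_mode, q_mode, tel_p, tel_q, sample_id=str(sample))
        if call is not None:
            call.centricity = classify_centricity(call, grp, centromeres)
            calls.append(call)
    return calls


def calls_to_frame(calls: list[IsoCall]) -> pd.DataFrame:
    cols = [
        "sample_id", "chrom", "loh_arm", "retained_arm", "iso_allele",
        "iso_allele_cn", "centricity", "fusion_site", "fusion_distance",
        "n_het_fragments", "data_gap",
    ]
    return pd.DataFrame([{c: getattr(k, c) for c in cols} for k in calls], columns=cols)
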