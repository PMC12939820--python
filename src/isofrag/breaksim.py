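"""Conditioned mean copy-number profiles and the single-break null model.

Telomere-anchored partial-arm deletions (the dominant pattern on chr3p in
clear-cell renal carcinoma) are modelled as one break per patient placed
uniformly inside a region [a, b] — the single event of a homogeneous
Poisson process conditioned on exactly one occurrence is uniform — with
the deletion spanning telomere to break.  The cohort mean copy number at
position x mixes break patients (copy 1 below their break, 2 at or above
it) with whole-arm-deletion patients (copy 1 everywhere):

    E[CN](x) = [n_break * (1 + F(x)) + n_full] / (n_break + n_full),

F the uniform CDF on [a, b].  At x = a the mean is 1 (every break lies
above a); at x = b it is (2 n_break + n_full) / (n_break + n_full).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class MeanProfile:
    chrom: str
    positions: np.ndarray
    mean_cn: np.ndarray
    n_patients: int


@dataclass
class BreakSimConfig:
    region_start: int          # telomere-side bound a (bp)
    region_end: int            # centromere-side bound b (bp)
    n_break_patients: int
    n_full_deletion_patients: int
    grid_step: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_start >= self.region_end:
            raise ValueError("region_start must be < region_end")
        if self.n_break_patients < 0 or self.n_full_deletion_patients < 0:
            raise ValueError("patient counts must be non-negative")
        if self.n_break_patients + self.n_full_deletion_patients == 0:
            raise ValueError("cohort is empty")


@dataclass
class BreakSimResult:
    positions: np.ndarray
    simulated_mean: np.ndarray
    analytic_mean: np.ndarray
    analytic_se: np.ndarray    # sd of the simulated mean at each position
    breaks: np.ndarray
    n_total: int


def conditioned_mean_profile(
    segments: pd.DataFrame,
    chrom: str,
    arm_start: int,
    arm_end: int,
    mode: str = "deletion",
    grid_step: int = 100_000,
) -> MeanProfile:
    """Mean total copy number over patients conditioned on an arm event.

    ``mode="deletion"`` keeps patients with any segment of total copy < 2
    overlapping [arm_start, arm_end); ``"amplification"`` keeps total > 2.
    The mean at each grid position is taken over included patients covered
    there.
    """
    if mode not in ("deletion", "amplification"):
        raise ValueError("mode must be 'deletion' or 'amplification'")
    on = segments[
        (segments["chrom"] == chrom)
        & (segments["end"] > arm_start)
        & (segments["start"] < arm_end)
    ]
    total = on["nMajor"] + on["nMinor"]
    hit = on.loc[total < 2 if mode == "deletion" else total > 2, "sample"].unique()
    if hit.size == 0:
        n_cohort = segments["sample"].nunique()
        raise ValueError(
            f"no patients satisfy the {mode} condition on {chrom}:"
            f"{arm_start}-{arm_end} (cohort of {n_cohort})"
        )
    positions = np.arange(arm_start, arm_end, grid_step, dtype=np.int64)
    acc = np.zeros(positions.size)
    cov = np.zeros(positions.size)
    for sample, grp in on[on["sample"].isin(hit)].groupby("sample", sort=False):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        tot = (g["nMajor"] + g["nMinor"]).to_numpy(dtype=float)
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        acc[valid] += tot[idx[valid]]
        cov[valid] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    return MeanProfile(chrom=chrom, positions=positions, mean_cn=mean, n_patients=int(hit.size))


def analytic_break_profile(
    config: BreakSimConfig, positions: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form mean and SE of the simulated mean on the grid."""
    a, b = config.region_start, config.region_end
    nb, nf = config.n_break_patients, config.n_full_deletion_patients
    n = nb + nf
    if positions is None:
        positions = np.arange(a, b + 1, config.grid_step, dtype=np.int64)
    F = np.clip((positions - a) / (b - a), 0.0, 1.0)
    mean = (nb * (1.0 + F) + nf) / n
    se = np.sqrt(nb * F * (1.0 - F)) / n
    return positions, mean, se


def simulate_poisson_breaks(
    config: BreakSimConfig, rng: Optional[np.random.Generator] = None
) -> BreakSimResult:
    """Draw one uniform break per patient and profile the cohort mean."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a, b = config.region_start, config.region_end
    nb, nf = config.n_break_patients, config.n_full_deletion_patients
    n = nb + nf
    breaks = rng.uniform(a, b, size=nb)
    positions, analytic, se = analytic_break_profile(config)
    # CN at x: break patients carry 1 below the break, 2 at/above it
    n_restored = (breaks[None, :] <= positions[:, None]).sum(axis=1)
    simulated = (nb + n_restored + nf) / n  # nb*1 + n_restored extra copies + nf*1
    return BreakSimResult(
        positions=positions,
        simulated_mean=simulated.astype(float),
        analytic_mean=analytic,
        analytic_se=se,
        breaks=breaks,
        n_total=n,
    )
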