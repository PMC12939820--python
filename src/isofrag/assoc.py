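"""Association between gene LOH / mutation status and isochromosome burden.

The central test is a two-proportion Wald contrast of per-chromosome
isochromosome occurrence between patients with and without LOH of a marker
gene.  Each patient contributes a fixed number of eligible chromosomes
(17 when the marker's own chromosome is excluded from the 18 screened
non-acrocentric chromosomes; 16 for a two-gene double-LOH contrast), so

    p_hat_1 = k1 / (c * N1),   p_hat_2 = k2 / (c * N2)

with k the isochromosome call counts, N the patient counts, and c the
chromosomes per patient.  The statistic uses the pooled proportion with
*patient* counts in the variance term,

    T = (p_hat_1 - p_hat_2) / sqrt(p_hat (1 - p_hat) (1/N1 + 1/N2)),

evaluated against a standard normal.  With c > 1 this variance overstates
the per-chromosome sampling noise by a factor of c, so the test is
conservative; a ``variance="trials"`` switch substitutes the trial counts
c*N for N.  Also here: BH false-discovery control, per-locus scans along a
chromosome, Fisher's exact test for mutation contrasts, occurrence
probability tables, cohort frequency arithmetic, and the bimodality index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .segio import HETEROZYGOUS, LOH, locus_loh_status

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    n1: int
    n2: int
    k1: int
    k2: int
    chroms_per_patient: int
    p_hat1: float
    p_hat2: float
    p_hat: float
    T: float
    p_value: float
    odds_ratio: float
    q_value: Optional[float] = None
    defined: bool = True
    reason: Optional[str] = None


def _wald_T_arrays(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray,
    chroms_per_patient: int, variance: str = "patients",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Wald statistic; returns (T, p_hat1, p_hat2, p_hat).

    Undefined entries (empty group or degenerate pooled proportion) are NaN.
    """
    c = chroms_per_patient
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = k1 / (c * n1)
        p2 = k2 / (c * n2)
        p = (k1 + k2) / (c * (n1 + n2))
        if variance == "patients":
            var = p * (1 - p) * (1.0 / n1 + 1.0 / n2)
        elif variance == "trials":
            var = p * (1 - p) * (1.0 / (c * n1) + 1.0 / (c * n2))
        else:
            raise ValueError(f"unknown variance convention {variance!r}")
        T = (p1 - p2) / np.sqrt(var)
    T = np.where((n1 > 0) & (n2 > 0) & (p > 0) & (p < 1), T, np.nan)
    return T, p1, p2, p


def wald_from_counts(
    k1: int, n1: int, k2: int, n2: int,
    chroms_per_patient: int = 17,
    variance: str = "patients",
) -> AssociationResult:
    """Two-proportion Wald test from pre-tallied counts."""
    T, p1, p2, p = (
        float(v[0])
        for v in _wald_T_arrays(
            np.array([k1], dtype=float), np.array([n1], dtype=float),
            np.array([k2], dtype=float), np.array([n2], dtype=float),
            chroms_per_patient, variance,
        )
    )
    reason = None
    if n1 == 0 or n2 == 0:
        reason = "empty group"
    elif not (0 < p < 1):
        reason = "pooled proportion degenerate"
    if reason is not None:
        return AssociationResult(
            n1, n2, k1, k2, chroms_per_patient,
            p1, p2, p, math.nan, math.nan, math.nan,
            defined=False, reason=reason,
        )
    p_value = 2.0 * stats.norm.sf(abs(T))
    if 0 < p1 < 1 and 0 < p2 < 1:
        odds_ratio = (p1 / (1 - p1)) / (p2 / (1 - p2))
    else:
        odds_ratio = math.inf if p1 > p2 else 0.0
    return AssociationResult(
        n1, n2, k1, k2, chroms_per_patient, p1, p2, p, T, p_value, odds_ratio
    )


def wald_loh_association(
    calls_by_patient: Mapping[str, int],
    status_by_patient: Mapping[str, str],
    chroms_per_patient: int = 17,
    variance: str = "patients",
) -> AssociationResult:
    """Wald association from per-patient isochromosome counts and LOH status.

    ``calls_by_patient`` maps patient -> number of isochromosome calls on
    the eligible chromosomes (the marker gene's own chromosome must already
    be excluded); ``status_by_patient`` maps patient -> LOH/heterozygous.
    Patients with ``no_data`` status are dropped.
    """
    k1 = n1 = k2 = n2 = 0
    for patient, k in calls_by_patient.items():
        status = status_by_patient.get(patient)
        if status == LOH:
            n1 += 1
            k1 += k
        elif status == HETEROZYGOUS:
            n2 += 1
            k2 += k
    return wald_from_counts(k1, n1, k2, n2, chroms_per_patient, variance)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass
class ScanProfile:
    chrom: str
    positions: np.ndarray
    T: np.ndarray
    p_values: np.ndarray          # one-sided upper tail
    neglog10_p: np.ndarray
    smoothed: np.ndarray
    n_informative: np.ndarray     # patients with LOH or het status per position


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with truncated windows; NaNs excluded."""
    n = values.size
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i - half + window)
        chunk = values[lo:hi]
        good = ~np.isnan(chunk)
        if good.any():
            out[i] = chunk[good].mean()
    return out


def locus_scan(
    segments: pd.DataFrame,
    calls_by_patient: Mapping[str, int],
    chrom: str,
    chrom_length: int,
    chroms_per_patient: int,
    step: int = 100_000,
    window: int = 20,
    variance: str = "patients",
) -> ScanProfile:
    """Scan a chromosome for positions whose LOH predicts isochromosomes.

    At every ``step`` bp the cohort is partitioned by LOH status at that
    locus and the Wald statistic computed against the per-patient call
    counts (which must exclude the scanned chromosome).  The scan direction
    of interest is excess occurrence in the LOH group, so p-values are
    one-sided upper tail; the -log10 p track is smoothed with a centred
    running mean of ``window`` bins.
    """
    positions = np.arange(0, chrom_length, step, dtype=np.int64)
    patients = list(calls_by_patient)
    counts = np.array([calls_by_patient[s] for s in patients], dtype=float)

    # status matrix via per-patient step functions over the scanned chromosome
    status = np.full((len(patients), positions.size), -1, dtype=np.int8)  # -1 no_data
    chrom_segs = segments[segments["chrom"] == chrom]
    grouped = dict(tuple(chrom_segs.groupby("sample", sort=False)))
    for i, patient in enumerate(patients):
        grp = grouped.get(patient)
        if grp is None:
            continue
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        minor = g["nMinor"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        loh = valid & (minor[np.clip(idx, 0, None)] == 0)
        status[i, valid & ~loh] = 0
        status[i, loh] = 1

    is_loh = status == 1
    is_het = status == 0
    n1 = is_loh.sum(axis=0).astype(float)
    n2 = is_het.sum(axis=0).astype(float)
    k1 = (is_loh * counts[:, None]).sum(axis=0)
    k2 = (is_het * counts[:, None]).sum(axis=0)
    T, _, _, _ = _wald_T_arrays(k1, n1, k2, n2, chroms_per_patient, variance)
    with np.errstate(invalid="ignore"):
        p = stats.norm.sf(T)
        neglog = -np.log10(p)
    neglog[~np.isfinite(neglog)] = np.nan
    return ScanProfile(
        chrom=chrom,
        positions=positions,
        T=T,
        p_values=p,
        neglog10_p=neglog,
        smoothed=running_mean(neglog, window),
        n_informative=(n1 + n2).astype(np.int64),
    )


def fisher_association(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test plus the sample odds ratio ad/bc.

    Returns (p, odds_ratio, continuity_used); a Haldane 0.5 is added to
    every cell for the odds ratio only when a zero cell makes ad/bc
    undefined, and the flag records that this happened.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    continuity = False
    if b * c == 0:  # ad/bc undefined only when the denominator vanishes
        continuity = True
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    return p, float(odds_ratio), continuity


def occurrence_table(
    cohorts: Mapping[str, tuple[Mapping[str, int], int]]
) -> pd.DataFrame:
    """Per-cohort isochromosome occurrence probabilities with a pooled column.

    ``cohorts`` maps cohort name -> (counts per isochromosome key, total
    patients).  The ``all`` column divides summed occurrences by summed
    patients.  Cohorts with zero patients are excluded with a warning.
    """
    usable = {}
    for name, (counts, total) in cohorts.items():
        if total <= 0:
            log.warning("cohort %s has no patients; excluded", name)
            continue
        usable[name] = (counts, total)
    if not usable:
        raise ValueError("no usable cohorts")
    keys = sorted({k for counts, _ in usable.values() for k in counts})
    out = pd.DataFrame(index=keys)
    for name, (counts, total) in usable.items():
        out[name] = [counts.get(k, 0) / total for k in keys]
    grand_total = sum(total for _, total in usable.values())
    out["all"] = [
        sum(counts.get(k, 0) for counts, _ in usable.values()) / grand_total
        for k in keys
    ]
    return out


def cohort_frequency(numerator: int, denominator: int) -> float:
    """Percentage numerator/denominator, half-up rounded to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    q = Fraction(100 * numerator, denominator)
    return float(math.floor(q * 10 + Fraction(1, 2))) / 10


def combine_frequencies(parts: Sequence[tuple[int, int]]) -> tuple[int, int, float]:
    """Pool (numerator, denominator) pairs, then take the percentage."""
    num = sum(n for n, _ in parts)
    den = sum(d for _, d in parts)
    return num, den, cohort_frequency(num, den)


@dataclass
class BimodalFit:
    m1: float
    m2: float
    sd: float
    pi: float
    delta: float
    bi: float
    is_bimodal: bool
    converged: bool

    CUTOFF = 1.1


def bimodality_index(
    values: Sequence[float], n_init: int = 5, random_state: int = 0
) -> BimodalFit:
    """Bimodality index from an equal-variance two-component normal mixture.

    BI = sqrt(pi * (1 - pi)) * |m1 - m2| / sd, with the recommended cutoff
    of 1.1 for declaring a distribution bimodal.  The mixture is fitted by
    EM with ``n_init`` seeded restarts.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 values")
    gm = GaussianMixture(
        n_components=2, covariance_type="tied",
        n_init=n_init, random_state=random_state,
    ).fit(x)
    m1, m2 = float(gm.means_[0, 0]), float(gm.means_[1, 0])
    sd = float(np.sqrt(gm.covariances_[0, 0]))
    pi = float(gm.weights_[0])
    delta = abs(m1 - m2) / sd
    bi = delta * math.sqrt(pi * (1 - pi))
    return BimodalFit(
        m1=m1, m2=m2, sd=sd, pi=pi, delta=delta, bi=bi,
        is_bimodal=bi >= BimodalFit.CUTOFF,
        converged=bool(gm.converged_),
    )


def loh_status_by_patient(
    segments: pd.DataFrame, chrom: str, start: int, end: int
) -> dict[str, str]:
    """Locus LOH status for every sample in a cohort segment table."""
    out: dict[str, str] = {}
    for sample, grp in segments.groupby("sample", sort=False):
        out[str(sample)] = locus_loh_status(grp, chrom, start, end)
    return out
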