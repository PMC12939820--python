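"""Fragmentation statistics of isochromosome LOH arms.

A dicentric isochromosome is pulled to both spindle poles and forms a
chromatin bridge whose rupture shatters the region between the fusion site
and the centromere.  The surviving shards appear in allele-specific copy
number as heterozygous fragments (minor copy > 0) embedded in the LOH arm.
This module counts those fragments, locates the fusion site, regresses
fragment counts on fusion distance, compares fragmentation between
dicentric isochromosomes and non-isochromosomes, and fits the Mott
fragment-size law N(L) = N0 * exp(-mu * L**beta) of dynamically fractured
solids to the cumulative size distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gamma as gamma_fn

from .isocall import DICENTRIC, MONOCENTRIC, IsoCall
from .segio import CentromereMap, coalesce_segments

log = logging.getLogger(__name__)

_INT_MAX = np.iinfo(np.int64).max


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be computed."""


@dataclass
class FragmentSet:
    """Heterozygous fragments fully inside one call's LOH arm.

    ``n_het_fragments`` is the fragment count plus one for the centromere
    region itself, minus a correction of one when the centromere is not
    spanned by a single segment but its flanking segments carry equal copy
    numbers (a missing-data artifact, not a real fragment boundary).
    """

    sample_id: str
    chrom: str
    loh_arm: str
    fragments: pd.DataFrame  # columns start, end, nMajor, nMinor
    n_het_fragments: int
    centromere_gap_corrected: bool

    @property
    def fragment_lengths(self) -> np.ndarray:
        if self.fragments.empty:
            return np.array([], dtype=np.int64)
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()


@dataclass
class RegressionFit:
    slope: float  # fragments per bp
    intercept: float
    slope_ci: tuple[float, float]
    n: int

    @property
    def mb_per_fragment(self) -> float:
        return 1.0 / (self.slope * 1e6)


@dataclass
class MottFit:
    mu: float
    beta: float
    log_n0: float
    rss: float
    n_points: int
    n_fragments: int
    scale: float  # bp per fitted length unit
    mu_se: float = math.nan
    beta_se: float = math.nan

    @property
    def mean_fragment_size(self) -> float:
        """Mean of the implied size density, mu**(-1/beta) * Gamma(1 + 1/beta)."""
        return self.mu ** (-1.0 / self.beta) * gamma_fn(1.0 + 1.0 / self.beta)

    def beta_ci(self, z: float = 1.96) -> tuple[float, float]:
        return self.beta - z * self.beta_se, self.beta + z * self.beta_se


def _arm_bounds(loh_arm: str, midpoint: int) -> tuple[int, int]:
    return (0, midpoint) if loh_arm == "p" else (midpoint, _INT_MAX)


def het_fragments(
    chrom_segments: pd.DataFrame, loh_arm: str, midpoint: int
) -> pd.DataFrame:
    """Segments with minor copy > 0 entirely contained in the LOH arm."""
    lo, hi = _arm_bounds(loh_arm, midpoint)
    keep = (
        (chrom_segments["nMinor"] > 0)
        & (chrom_segments["start"] >= lo)
        & (chrom_segments["end"] <= hi)
    )
    return chrom_segments.loc[keep, ["start", "end", "nMajor", "nMinor"]].sort_values("start")


def _centromere_gap_correction(
    chrom_segments: pd.DataFrame, cen_start: int, cen_end: int
) -> bool:
    """True when the centromere is unspanned but its flanks have equal copy.

    Array platforms have no probes in centromeric repeats, so a segment
    boundary falling inside the centromere with identical copy numbers on
    both sides indicates missing data rather than a fragmentation event.
    """
    spanned = (
        (chrom_segments["start"] <= cen_start) & (chrom_segments["end"] >= cen_end)
    ).any()
    if spanned:
        return False
    before = chrom_segments[chrom_segments["end"] <= cen_start]
    after = chrom_segments[chrom_segments["start"] >= cen_end]
    if before.empty or after.empty:
        return False
    b = before.loc[before["end"].idxmax()]
    a = after.loc[after["start"].idxmin()]
    return bool(b["nMajor"] == a["nMajor"] and b["nMinor"] == a["nMinor"])


def count_het_fragments(
    call: IsoCall, chrom_segments: pd.DataFrame, centromeres: CentromereMap
) -> FragmentSet:
    """Count heterozygous fragments on the call's LOH arm.

    Adds one for the centromere region itself and subtracts one under the
    centromere missing-data correction; the count never drops below one.
    """
    span = centromeres[call.chrom]
    frags = het_fragments(chrom_segments, call.loh_arm, span.midpoint)
    corrected = _centromere_gap_correction(chrom_segments, span.cen_start, span.cen_end)
    n = len(frags) + 1 - int(corrected)
    return FragmentSet(
        sample_id=call.sample_id,
        chrom=call.chrom,
        loh_arm=call.loh_arm,
        fragments=frags.reset_index(drop=True),
        n_het_fragments=max(1, n),
        centromere_gap_corrected=corrected,
    )


def locate_fusion_site(
    call: IsoCall, fragments: FragmentSet, centromeres: CentromereMap
) -> tuple[int, int]:
    """Fusion site and its distance from the centromere midpoint.

    The fusion site is the telomere-facing boundary of the heterozygous
    fragment farthest from the centromere midpoint; with no fragments the
    isochromosome is fused at the centromere (distance 0).
    """
    mid = centromeres.midpoint(call.chrom)
    if fragments.fragments.empty:
        return mid, 0
    if call.loh_arm == "q":
        site = int(fragments.fragments["end"].max())
        return site, site - mid
    site = int(fragments.fragments["start"].min())
    return site, mid - site


def annotate_calls(
    calls: Sequence[IsoCall],
    segments: pd.DataFrame,
    centromeres: CentromereMap,
) -> list[FragmentSet]:
    """Fill fragment counts, fusion sites and centricity on a list of calls.

    Mutates the calls in place and returns the per-call fragment sets.
    Centricity follows the whole-arm-LOH rule: no heterozygous fragment on
    the LOH arm means monocentric, otherwise dicentric.
    """
    segments = coalesce_segments(segments)
    grouped = dict(tuple(segments.groupby(["sample", "chrom"], sort=False)))
    out: list[FragmentSet] = []
    for call in calls:
        grp = grouped[(call.sample_id, call.chrom)]
        fs = count_het_fragments(call, grp, centromeres)
        site, dist = locate_fusion_site(call, fs, centromeres)
        call.n_het_fragments = fs.n_het_fragments
        call.fusion_site = site
        call.fusion_distance = dist
        call.centricity = MONOCENTRIC if fs.fragments.empty else DICENTRIC
        call.data_gap = fs.centromere_gap_corrected
        out.append(fs)
    return out


def regress_fragment_count(
    fusion_distances_bp: Sequence[float], fragment_counts: Sequence[float]
) -> RegressionFit:
    """OLS of heterozygous fragment count on fusion-site distance.

    The slope estimates the bridge fragmentation rate in fragments per bp;
    its reciprocal (in Mb) is the mean spacing between new fragments.
    """
    x = np.asarray(fusion_distances_bp, dtype=float)
    y = np.asarray(fragment_counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calls to regress fragment counts")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all fusion distances identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n=int(x.size),
    )


def compare_fragmentation(
    dicentric_counts: Sequence[float],
    noniso_counts: Sequence[float],
    method: str = "auto",
) -> tuple[float, float, float]:
    """Mann-Whitney U comparison of fragment counts plus mean fold change.

    Returns (U, two-sided p, fold) with fold = mean(dicentric)/mean(noniso).
    """
    x = np.asarray(dicentric_counts, dtype=float)
    y = np.asarray(noniso_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    fold = float(x.mean() / y.mean())
    return float(res.statistic), float(res.pvalue), fold


def empirical_cumulative_counts(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """N(L) = number of fragments with length strictly greater than L.

    Evaluated at each distinct observed length (no binning); the largest
    length, where N(L) = 0, is excluded because the fit runs on log N.
    """
    ls = np.unique(np.asarray(lengths, dtype=float))
    n_gt = np.array([(lengths > l).sum() for l in ls], dtype=float)
    keep = n_gt > 0
    return ls[keep], n_gt[keep]


def _mott_log_survival(L: np.ndarray, log_n0: float, mu: float, beta: float) -> np.ndarray:
    return log_n0 - mu * np.power(L, beta)


def fit_mott(
    fragment_lengths_bp: Sequence[float],
    scale: float = 1e6,
    beta_starts: Sequence[float] = (0.5, 1.0, 1.5),
) -> tuple[MottFit, MottFit]:
    """Fit the Mott law to the cumulative fragment-size distribution.

    log N(L) = log N0 - mu * L**beta is fitted by nonlinear least squares
    on the empirical cumulative counts, restarting from several beta
    values.  Points are weighted by their count N(L) — the inverse of the
    approximate variance of log N(L) — so the sparse far tail does not
    dominate the fit.  Parameter standard errors use a sandwich estimator
    with the known covariance of empirical log-survival counts,
    Cov(log N_i, log N_j) ~= 1/max(N_i, N_j) - 1/n, which accounts for
    the serial correlation of cumulative counts.

    A second, constrained fit with beta = 1 (the homogeneous
    Poisson-process / exponential case) shares the unconstrained fit's
    estimated mean fragment size, isolating the shape comparison; its only
    free parameter, log N0, has a closed-form weighted least-squares
    solution.  Both fits report the same weighted RSS objective.

    Lengths are taken in bp and fitted on L/scale (default Mb), so mu is
    reported per (scale bp)**beta.  Returns (mott_fit, exponential_fit).
    """
    lengths = np.asarray(fragment_lengths_bp, dtype=float)
    if lengths.size < 10:
        raise ValueError("need at least 10 fragment lengths")
    if (lengths <= 0).any():
        raise ValueError("fragment lengths must be positive")
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate input: all fragment lengths equal")
    n_total = lengths.size
    lengths = lengths / scale
    ls, n_gt = empirical_cumulative_counts(lengths)
    if ls.size < 3:
        raise ValueError("too few distinct lengths for a 3-parameter fit")
    log_n = np.log(n_gt)
    w = np.sqrt(n_gt)  # residual scaling; squared weight = N
    mean_len = float(lengths.mean())

    def residuals(params: np.ndarray) -> np.ndarray:
        return w * (log_n - _mott_log_survival(ls, *params))

    best: Optional[optimize.OptimizeResult] = None
    tried = []
    for beta0 in beta_starts:
        p0 = (math.log(n_total), 1.0 / mean_len, beta0)
        tried.append(p0)
        try:
            res = optimize.least_squares(
                residuals, x0=p0,
                bounds=([-np.inf, 1e-12, 1e-6], [np.inf, np.inf, 10.0]),
                max_nfev=20000,
            )
        except ValueError:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"Mott fit failed to converge from starts {tried}")
    log_n0, mu, beta = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)

    # sandwich covariance: A = J'WJ, B = J'W Sigma W J with the closed-form
    # covariance of the empirical log-survival curve
    Lb = np.power(ls, beta)
    J = np.column_stack([np.ones_like(ls), -Lb, -mu * Lb * np.log(ls)])
    W = n_gt
    sigma = 1.0 / np.maximum.outer(n_gt, n_gt) - 1.0 / n_total
    A = J.T @ (W[:, None] * J)
    B = J.T @ (W[:, None] * sigma * W[None, :]) @ J
    try:
        a_inv = np.linalg.inv(A)
        cov = a_inv @ B @ a_inv
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        mu_se, beta_se = float(se[1]), float(se[2])
    except np.linalg.LinAlgError:
        mu_se = beta_se = math.nan

    mott = MottFit(
        mu=mu, beta=beta, log_n0=log_n0,
        rss=rss, n_points=int(ls.size), n_fragments=int(n_total), scale=scale,
        mu_se=mu_se, beta_se=beta_se,
    )

    # beta = 1 comparison sharing the Mott fit's estimated mean: mean = 1/mu_exp
    mu_exp = 1.0 / mott.mean_fragment_size
    log_n0_exp = float(np.average(log_n + mu_exp * ls, weights=n_gt))
    rss_exp = float(np.sum(n_gt * (log_n - (log_n0_exp - mu_exp * ls)) ** 2))
    expo = MottFit(
        mu=mu_exp, beta=1.0, log_n0=log_n0_exp,
        rss=rss_exp, n_points=int(ls.size), n_fragments=int(n_total), scale=scale,
    )
    return mott, expo
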