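"""Synthetic cohorts and effect matrices with known ground truth.

The generator emits ASCAT-style allele-specific segment tables over a
small synthetic genome (three metacentric chromosomes plus one
submetacentric marker chromosome) together with a truth table, so that
every downstream operation — isochromosome calling, centricity, fusion
sites, fragment counts, LOH association — can be validated by oracle
equivalence rather than against irreproducible cohort downloads.

Planted events:

* monocentric isochromosome: whole-arm LOH at copy (1, 0) opposite a
  retained arm at (2, 1) — the duplicated (major) allele at two copies;
* dicentric isochromosome: a fusion site drawn on the LOH arm, LOH distal
  to it, and the bridged span between centromere and fusion carrying
  interleaved heterozygous fragments at (1, 1) whose sizes follow a Mott
  law and whose count is one deterministic fragment anchored at the
  fusion site plus a Poisson number at the configured fragmentation rate
  (so an OLS slope of count on fusion distance estimates the rate without
  bias);
* marker-gene LOH coupled to the per-chromosome isochromosome probability
  at a configurable odds ratio, for association recovery tests;
* a factor-model gene-effect matrix whose hub gene loads on two
  sub-factors that each drive half of the spoke genes, so shortest paths
  between the two spoke clusters run through the hub.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .segio import SEGMENT_COLUMNS, CentromereMap, CentromereSpan

MB = 1_000_000


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cen_start: int
    cen_end: int

    @property
    def midpoint(self) -> int:
        return (self.cen_start + self.cen_end) // 2


@dataclass
class Genome:
    chromosomes: dict[str, Chromosome]

    def centromere_map(self) -> CentromereMap:
        return CentromereMap(
            {c.name: CentromereSpan(c.name, c.cen_start, c.cen_end) for c in self.chromosomes.values()}
        )

    def arm_length(self, chrom: str, arm: str) -> int:
        c = self.chromosomes[chrom]
        return c.midpoint if arm == "p" else c.length - c.midpoint


def default_genome() -> Genome:
    """Bundled synthetic genome: 3 metacentric + 1 submetacentric chromosome."""
    chroms = [
        Chromosome("c1", 200 * MB, 95 * MB, 105 * MB),
        Chromosome("c2", 160 * MB, 75 * MB, 85 * MB),
        Chromosome("c3", 130 * MB, 60 * MB, 70 * MB),
        Chromosome("c4", 120 * MB, 30 * MB, 40 * MB),  # submetacentric; marker
    ]
    return Genome({c.name: c for c in chroms})


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``frag_rate`` is the expected number of bridge fragments per bp of
    fusion distance (default one per 12 Mb, the empirically observed
    spacing); fragment sizes follow a Mott law with ``mott_mu`` per
    Mb**beta and shape ``mott_beta``.  ``coupling_or`` is the odds ratio
    linking marker-gene LOH to the per-chromosome isochromosome
    probability ``p_iso``.
    """

    n_patients: int = 200
    genome: Genome = field(default_factory=default_genome)
    p_iso: float = 0.1
    p_mono: float = 0.4
    frag_rate: float = 1.0 / (12 * MB)
    mott_mu: float = 0.9          # per Mb**beta
    mott_beta: float = 0.7
    marker_chrom: str = "c4"
    marker_start: int = 60 * MB
    marker_end: int = 62 * MB
    marker_loh_prevalence: float = 0.3
    coupling_or: float = 1.0
    min_fusion_distance: int = 10 * MB
    telomere_margin: int = 5 * MB
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_iso", "p_mono", "marker_loh_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mott_mu <= 0 or self.mott_beta <= 0:
            raise ValueError("Mott parameters must be positive")
        if self.coupling_or <= 0:
            raise ValueError("coupling odds ratio must be positive")
        if self.frag_rate < 0:
            raise ValueError("fragmentation rate must be non-negative")


TRUTH_COLUMNS = [
    "sample", "chrom", "iso", "loh_arm", "centricity", "fusion_site",
    "fusion_distance", "n_het_fragments", "marker_loh",
]


def sample_mott_lengths(
    n: int, mu: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw fragment lengths (in the units of mu**(-1/beta)) from the Mott law.

    Survival S(L) = exp(-mu * L**beta) inverts to L = (-ln U / mu)**(1/beta).
    """
    u = rng.random(n)
    return np.power(-np.log(u) / mu, 1.0 / beta)


def coupled_iso_probability(p_base: float, odds_ratio: float) -> float:
    """Per-chromosome event probability in the marker-LOH group.

    Shifts the baseline log-odds by log(odds_ratio).
    """
    odds = odds_ratio * p_base / (1.0 - p_base)
    return odds / (1.0 + odds)


def _plant_dicentric(
    chrom: Chromosome, arm: str, spec: CohortSpec, rng: np.random.Generator
) -> tuple[list[tuple[int, int, int, int]], int, int]:
    """Segments for one dicentric isochromosome chromosome.

    Returns (segments as (start, end, major, minor), fusion_site, n_fragments).
    One fragment is anchored with its outer boundary at the fusion site;
    Poisson(rate * distance) extra fragments fill the bridged span.
    """
    mid = chrom.midpoint
    arm_len = spec.genome.arm_length(chrom.name, arm)
    d_max = arm_len - spec.telomere_margin
    if d_max <= spec.min_fusion_distance:
        raise ValueError(f"arm {chrom.name}{arm} too short for a dicentric plant")
    d = int(rng.uniform(spec.min_fusion_distance, d_max))
    n_extra = int(rng.poisson(spec.frag_rate * d))
    # fragments must fit in the bridge and keep the arm's modal minor at 0;
    # resampling sizes (not the count) keeps E[count | d] linear in d
    cap = min(0.8 * d, 0.45 * arm_len)
    sizes = None
    for _ in range(50):
        draw = np.maximum(
            1, np.round(sample_mott_lengths(n_extra + 1, spec.mott_mu, spec.mott_beta, rng) * MB)
        ).astype(np.int64)
        if draw.sum() < cap:
            sizes = draw
            break
    if sizes is None:
        sizes = np.array([max(1, d // 4)], dtype=np.int64)
        n_extra = 0
    outer = int(sizes[0])
    inner = sizes[1:]
    # distribute the inner fragments over [0, d - outer) with positive gaps
    free = d - outer - int(inner.sum())
    gaps = rng.dirichlet(np.ones(len(inner) + 1)) * free if free > 0 else np.zeros(len(inner) + 1)
    cleaned: list[tuple[int, int]] = []  # offsets from centromere midpoint
    cur = 0
    for g, s in zip(gaps[:-1], inner):
        start = cur + max(1, int(g))
        end = start + int(s)
        if end <= d - outer - 1:  # never collide with the fusion-site anchor
            cleaned.append((start, end))
            cur = end
    cleaned.append((d - outer, d))

    def q_pos(off: int) -> int:
        return mid + off

    def p_pos(off: int) -> int:
        return mid - off

    segs: list[tuple[int, int, int, int]] = []
    if arm == "q":
        segs.append((0, mid, 2, 1))  # retained p arm
        cur = mid
        for a, b in cleaned:
            if q_pos(a) > cur:
                segs.append((cur, q_pos(a), 1, 0))
            segs.append((q_pos(a), q_pos(b), 1, 1))
            cur = q_pos(b)
        if cur < chrom.length:
            segs.append((cur, chrom.length, 1, 0))
        fusion_site = q_pos(d)
    else:
        cur = 0
        mirrored = sorted((p_pos(b), p_pos(a)) for a, b in cleaned)
        for a, b in mirrored:
            if a > cur:
                segs.append((cur, a, 1, 0))
            segs.append((a, b, 1, 1))
            cur = b
        if cur < mid:
            segs.append((cur, mid, 1, 0))
        segs.append((mid, chrom.length, 2, 1))  # retained q arm
        fusion_site = p_pos(d)
    return segs, fusion_site, len(cleaned)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort segment table and its truth table.

    Background is diploid (1, 1); the marker chromosome carries an LOH
    segment over the marker gene in marker-LOH patients and never hosts a
    planted isochromosome.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p_loh_group = coupled_iso_probability(spec.p_iso, spec.coupling_or)
    seg_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for i in range(spec.n_patients):
        sample = f"S{i:04d}"
        marker_loh = bool(rng.random() < spec.marker_loh_prevalence)
        p_iso_patient = p_loh_group if marker_loh else spec.p_iso
        for chrom in spec.genome.chromosomes.values():
            if chrom.name == spec.marker_chrom:
                if marker_loh:
                    ext_l = int(rng.uniform(0, MB))
                    ext_r = int(rng.uniform(0, MB))
                    a = max(0, spec.marker_start - ext_l)
                    b = min(chrom.length, spec.marker_end + ext_r)
                    if a > 0:
                        seg_rows.append((sample, chrom.name, 0, a, 1, 1))
                    seg_rows.append((sample, chrom.name, a, b, 1, 0))
                    if b < chrom.length:
                        seg_rows.append((sample, chrom.name, b, chrom.length, 1, 1))
                else:
                    seg_rows.append((sample, chrom.name, 0, chrom.length, 1, 1))
                truth_rows.append(
                    (sample, chrom.name, False, None, None, None, None, None, marker_loh)
                )
                continue
            if rng.random() >= p_iso_patient:
                seg_rows.append((sample, chrom.name, 0, chrom.length, 1, 1))
                truth_rows.append(
                    (sample, chrom.name, False, None, None, None, None, None, marker_loh)
                )
                continue
            loh_arm = "p" if rng.random() < 0.5 else "q"
            mid = chrom.midpoint
            if rng.random() < spec.p_mono:
                if loh_arm == "p":
                    seg_rows.append((sample, chrom.name, 0, mid, 1, 0))
                    seg_rows.append((sample, chrom.name, mid, chrom.length, 2, 1))
                else:
                    seg_rows.append((sample, chrom.name, 0, mid, 2, 1))
                    seg_rows.append((sample, chrom.name, mid, chrom.length, 1, 0))
                truth_rows.append(
                    (sample, chrom.name, True, loh_arm, "monocentric", mid, 0, 1, marker_loh)
                )
            else:
                segs, fusion_site, n_frags = _plant_dicentric(chrom, loh_arm, spec, rng)
                for s, e, maj, mino in segs:
                    seg_rows.append((sample, chrom.name, s, e, maj, mino))
                truth_rows.append(
                    (
                        sample, chrom.name, True, loh_arm, "dicentric",
                        fusion_site, abs(fusion_site - mid), n_frags + 1, marker_loh,
                    )
                )
    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return segments, truth


def simulate_association_counts(
    n1: int,
    n2: int,
    p_base: float,
    odds_ratio: float,
    chroms_per_patient: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Isochromosome call counts for an LOH group and a heterozygous group.

    Each patient contributes ``chroms_per_patient`` independent Bernoulli
    chromosomes at the baseline probability (heterozygous group) or the
    odds-shifted probability (LOH group).
    """
    p1 = coupled_iso_probability(p_base, odds_ratio)
    k1 = int(rng.binomial(chroms_per_patient * n1, p1))
    k2 = int(rng.binomial(chroms_per_patient * n2, p_base))
    return k1, k2


@dataclass
class EffectMatrixTruth:
    hub: str
    loadings: pd.DataFrame          # genes x factors
    population_corr: pd.DataFrame   # implied by the loadings (noise_sd = 0)


def generate_effect_matrix(
    n_genes: int = 11,
    n_cell_lines: int = 200,
    hub_gene: str = "HUB",
    hub_loading: float = 0.9,
    spoke_loading: float = 0.85,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, EffectMatrixTruth]:
    """Factor-model gene-effect matrix with a planted hub.

    Two latent factors each drive half of the spoke genes; the hub loads
    equally on both (split as hub_loading/sqrt(2) per factor), so the hub
    correlates with every spoke while cross-cluster spokes are
    uncorrelated up to noise — shortest penalty paths between the clusters
    pass through the hub.  Idiosyncratic variance tops each gene up to
    unit variance, so with ``noise_sd = 0`` the population correlation of
    two genes is exactly the inner product of their loading rows.
    """
    if n_genes < 5:
        raise ValueError("need at least 5 genes")
    if not (0 < hub_loading < 1 and 0 < spoke_loading < 1):
        raise ValueError("loadings must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_spokes = n_genes - 1
    half = n_spokes // 2
    genes = [hub_gene] + [f"SPA{i}" for i in range(half)] + [
        f"SPB{i}" for i in range(n_spokes - half)
    ]
    load = np.zeros((n_genes, 2))
    load[0, :] = hub_loading / math.sqrt(2)
    load[1 : 1 + half, 0] = spoke_loading
    load[1 + half :, 1] = spoke_loading
    idio = np.sqrt(1.0 - (load ** 2).sum(axis=1))
    factors = rng.standard_normal((2, n_cell_lines))
    eps = rng.standard_normal((n_genes, n_cell_lines))
    data = load @ factors + idio[:, None] * eps
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    matrix = pd.DataFrame(data, index=genes, columns=[f"CL{j:04d}" for j in range(n_cell_lines)])
    pop_corr = pd.DataFrame(load @ load.T + np.diag(idio ** 2), index=genes, columns=genes)
    truth = EffectMatrixTruth(
        hub=hub_gene,
        loadings=pd.DataFrame(load, index=genes, columns=["f1", "f2"]),
        population_corr=pop_corr,
    )
    return matrix, truth
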