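"""f2/f3/f4 and Patterson's D statistics with weighted block-jackknife SEs.

All statistics are ratios (or means) of per-site terms computed from sample
allele frequencies.  Standard errors come from a delete-one-block weighted
jackknife over contiguous genomic blocks, with block weights proportional to
the number of usable SNPs per block; blocks never span chromosome
boundaries.  The weighted-jackknife variance is the Busing et al. (1999)
estimator, which reduces exactly to the textbook delete-one formula under
equal block weights.

Sign convention: ``D(W, X; Y, Z) > 0`` means the "test" population Y (third
slot) shares excess alleles with W.  Per-site terms, with population
frequencies w, x, y, z:

=========  =====================================  ==========================
statistic  numerator                              denominator
=========  =====================================  ==========================
D          (w - x)(y - z)                         (w + x - 2wx)(y + z - 2yz)
f4         (w - x)(y - z)                         1 (mean)
f3(T;A,B)  (t - a)(t - b)                         1 (mean)
f2         (a - b)^2                              1 (mean)
=========  =====================================  ==========================

A usable site for a statistic is one where every involved population has at
least one observed allele (complete cases per statistic, not a global
intersection).  Sample frequencies enter D/f4 without bias correction (both
are unbiased in the frequencies); for f2/f3 an optional small-sample
heterozygosity correction is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .eigendata import GenotypeDataset, PopulationFrequencies, allele_frequencies

DEFAULT_BLOCK_SIZE_MORGANS = 0.05
DEFAULT_FALLBACK_BLOCK_SIZE_BP = 5_000_000
DEFAULT_MIN_SNPS = 30_000


@dataclass
class BlockAssignment:
    """Per-SNP block indices for the jackknife."""

    block_index: np.ndarray  # (n_snps,) int
    n_blocks: int
    unit: str  # "morgans" | "bp"
    block_size: float

    @property
    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.block_index, minlength=self.n_blocks)


def assign_blocks(
    snps,
    block_size_morgans: float = DEFAULT_BLOCK_SIZE_MORGANS,
    fallback_block_size_bp: int = DEFAULT_FALLBACK_BLOCK_SIZE_BP,
) -> BlockAssignment:
    """Group consecutive SNPs into jackknife blocks.

    Blocks span at most ``block_size_morgans`` of genetic distance when the
    genetic map is non-degenerate, else ``fallback_block_size_bp`` of physical
    distance; a new block starts at every chromosome boundary.

    ``snps`` may be a :class:`~fstatkit.eigendata.GenotypeDataset` or a list of
    SNP records.
    """
    if isinstance(snps, GenotypeDataset):
        snps = snps.snps
    chrom = np.array([s.chromosome for s in snps])
    ppos = np.array([s.physical_position for s in snps], dtype=np.int64)
    gpos = np.array([s.genetic_position for s in snps], dtype=float)

    # sortedness check (contiguous chromosome runs, nondecreasing positions)
    for arr, name in ((ppos, "physical"),):
        prev = None
        last = -1
        seen = set()
        for c, p in zip(chrom, arr):
            if c != prev:
                if c in seen:
                    raise ValueError("SNPs not grouped by chromosome")
                seen.add(c)
                prev, last = c, -1
            if p < last:
                raise ValueError(f"SNPs not sorted by {name} position on chromosome {c}")
            last = p

    use_genetic = _genetic_map_usable(chrom, gpos)
    pos = gpos if use_genetic else ppos.astype(float)
    size = block_size_morgans if use_genetic else float(fallback_block_size_bp)

    block = np.empty(len(snps), dtype=np.int64)
    b = -1
    prev_chrom = None
    start = 0.0
    for i in range(len(snps)):
        if chrom[i] != prev_chrom or pos[i] - start >= size:
            b += 1
            start = pos[i]
            prev_chrom = chrom[i]
        block[i] = b
    return BlockAssignment(
        block_index=block,
        n_blocks=b + 1,
        unit="morgans" if use_genetic else "bp",
        block_size=size,
    )


def _genetic_map_usable(chrom: np.ndarray, gpos: np.ndarray) -> bool:
    """A genetic map is usable if nondecreasing within chromosomes with a
    positive total span; all-zero (absent) maps fall back to physical."""
    if len(gpos) == 0 or (gpos < 0).any():
        return False
    span = 0.0
    for c in dict.fromkeys(chrom.tolist()):
        g = gpos[chrom == c]
        if (np.diff(g) < 0).any():
            return False
        span += g[-1] - g[0] if len(g) else 0.0
    return span > 0


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JackknifeResult:
    estimate: float
    se: float
    n_blocks: int


def jackknife(
    block_numerators: np.ndarray,
    block_denominators: np.ndarray,
    block_weights: np.ndarray | None = None,
) -> JackknifeResult:
    """Delete-one-block weighted jackknife for a ratio statistic.

    The estimate is the whole-data ratio; the variance is the weighted
    jackknife of Busing, Meijer & van der Leeden (1999) with weights
    proportional to per-block usable SNP counts (defaulting to the
    denominators).  Blocks with zero weight are dropped; at least two
    weighted blocks are required.
    """
    num = np.asarray(block_numerators, dtype=float)
    den = np.asarray(block_denominators, dtype=float)
    m = den.copy() if block_weights is None else np.asarray(block_weights, dtype=float)
    if not (num.shape == den.shape == m.shape):
        raise ValueError("block arrays must have matching shapes")
    keep = m > 0
    num, den, m = num[keep], den[keep], m[keep]
    g = len(m)
    if g < 2:
        raise ValueError(f"jackknife requires >= 2 blocks with positive weight, got {g}")
    tot_num, tot_den, n = num.sum(), den.sum(), m.sum()
    if tot_den == 0:
        raise ZeroDivisionError("degenerate statistic: total denominator is zero")
    theta = tot_num / tot_den
    loo_den = tot_den - den
    if (loo_den == 0).any():
        raise ZeroDivisionError("a delete-one-block replicate has zero denominator")
    theta_j = (tot_num - num) / loo_den
    h = n / m
    theta_dot = g * theta - ((1.0 - m / n) * theta_j).sum()
    pseudo = h * theta - (h - 1.0) * theta_j
    var = np.sum((pseudo - theta_dot) ** 2 / (h - 1.0)) / g
    return JackknifeResult(estimate=float(theta), se=float(math.sqrt(max(var, 0.0))), n_blocks=g)


def jackknife_covariance(
    block_vectors: np.ndarray,
    block_counts: np.ndarray,
    total_vector: np.ndarray,
    total_count: float,
) -> np.ndarray:
    """Weighted-jackknife covariance for a vector of per-site means.

    ``block_vectors`` holds per-block sums (g, d); the statistic is
    ``total_vector / total_count`` and delete-one replicates are
    ``(total - block) / (n - m_j)``.  Same pseudovalue weighting as
    :func:`jackknife`, applied per coordinate pair.
    """
    bs = np.asarray(block_vectors, dtype=float)
    m = np.asarray(block_counts, dtype=float)
    keep = m > 0
    bs, m = bs[keep], m[keep]
    g = len(m)
    if g < 2:
        raise ValueError("jackknife covariance requires >= 2 blocks")
    n = m.sum()
    theta = np.asarray(total_vector, dtype=float) / total_count
    loo = (total_vector[None, :] - bs) / (n - m)[:, None]
    h = n / m
    theta_dot = g * theta - ((1.0 - m / n)[:, None] * loo).sum(axis=0)
    pseudo = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo
    dev = pseudo - theta_dot[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / g
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# Blocked statistics
# ---------------------------------------------------------------------------


@dataclass
class BlockedFStat:
    """One f- or D-statistic with its block-jackknife summary."""

    kind: str  # "D" | "f4" | "f3" | "f2"
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    below_threshold: bool
    block_numerators: np.ndarray
    block_denominators: np.ndarray
    block_counts: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pops = ", ".join(self.populations)
        return (
            f"<{self.kind}({pops}) = {self.estimate:.6g} +/- {self.se:.3g} "
            f"(Z = {self.z:.2f}, {self.n_snps} SNPs, {self.n_blocks} blocks)>"
        )


def _zscore(estimate: float, se: float) -> float:
    if se > 0:
        return estimate / se
    return 0.0 if estimate == 0 else math.copysign(math.inf, estimate)


def _blocked_ratio(
    kind: str,
    populations: tuple[str, ...],
    site_num: np.ndarray,
    site_den: np.ndarray,
    usable: np.ndarray,
    blocks: BlockAssignment,
    min_snps: int,
) -> BlockedFStat:
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError(f"{kind}{populations}: zero usable SNPs")
    idx = blocks.block_index[usable]
    bnum = np.bincount(idx, weights=site_num[usable], minlength=blocks.n_blocks)
    bden = np.bincount(idx, weights=site_den[usable], minlength=blocks.n_blocks)
    bcnt = np.bincount(idx, minlength=blocks.n_blocks).astype(float)
    jk = jackknife(bnum, bden, bcnt)
    return BlockedFStat(
        kind=kind,
        populations=populations,
        estimate=jk.estimate,
        se=jk.se,
        z=_zscore(jk.estimate, jk.se),
        n_snps=n_usable,
        n_blocks=jk.n_blocks,
        below_threshold=n_usable <= min_snps,
        block_numerators=bnum,
        block_denominators=bden,
        block_counts=bcnt,
    )


def _freq_columns(
    dataset: GenotypeDataset,
    pops: Sequence[str],
    freqs: PopulationFrequencies | None,
) -> tuple[np.ndarray, np.ndarray]:
    table = freqs if freqs is not None else allele_frequencies(dataset, pops)
    cols = [table.column(p) for p in pops]
    return table.frequencies[:, cols], table.allele_counts[:, cols]


def d_statistic(
    dataset: GenotypeDataset,
    w: str,
    x: str,
    y: str,
    z: str,
    blocks: BlockAssignment,
    min_snps: int = DEFAULT_MIN_SNPS,
    freqs: PopulationFrequencies | None = None,
) -> BlockedFStat:
    """Patterson's D with weighted block-jackknife SE and Z score.

    ``freqs`` may carry precomputed population frequencies to amortize the
    tally across a batch of statistics.
    """
    f, c = _freq_columns(dataset, (w, x, y, z), freqs)
    usable = (c > 0).all(axis=1)
    fw, fx, fy, fz = (np.nan_to_num(f[:, i]) for i in range(4))
    num = (fw - fx) * (fy - fz)
    den = (fw + fx - 2 * fw * fx) * (fy + fz - 2 * fy * fz)
    return _blocked_ratio("D", (w, x, y, z), num, den, usable, blocks, min_snps)


def f4_statistic(
    dataset: GenotypeDataset,
    a: str,
    b: str,
    c: str,
    d: str,
    blocks: BlockAssignment,
    min_snps: int = DEFAULT_MIN_SNPS,
    freqs: PopulationFrequencies | None = None,
) -> BlockedFStat:
    """f4 = mean over usable sites of (a-b)(c-d); D's unnormalized numerator."""
    f, cnt = _freq_columns(dataset, (a, b, c, d), freqs)
    usable = (cnt > 0).all(axis=1)
    fa, fb, fc, fd = (np.nan_to_num(f[:, i]) for i in range(4))
    num = (fa - fb) * (fc - fd)
    return _blocked_ratio(
        "f4", (a, b, c, d), num, np.ones_like(num), usable, blocks, min_snps
    )


def f2_statistic(
    dataset: GenotypeDataset,
    a: str,
    b: str,
    blocks: BlockAssignment,
    min_snps: int = DEFAULT_MIN_SNPS,
    corrected: bool = False,
    freqs: PopulationFrequencies | None = None,
) -> BlockedFStat:
    """f2 = mean (a-b)^2, optionally with the heterozygosity bias correction.

    The corrected estimator subtracts ``h_a/n_a + h_b/n_b`` per site with
    ``h = p(1-p) n/(n-1)``; sites with fewer than two observed alleles in
    either population are unusable in corrected mode.
    """
    f, cnt = _freq_columns(dataset, (a, b), freqs)
    usable = (cnt > (1 if corrected else 0)).all(axis=1)
    fa, fb = np.nan_to_num(f[:, 0]), np.nan_to_num(f[:, 1])
    num = (fa - fb) ** 2
    if corrected:
        na, nb = cnt[:, 0], cnt[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            num = num - _het_over_n(fa, na) - _het_over_n(fb, nb)
    return _blocked_ratio("f2", (a, b), num, np.ones_like(num), usable, blocks, min_snps)


def f3_statistic(
    dataset: GenotypeDataset,
    target: str,
    a: str,
    b: str,
    blocks: BlockAssignment,
    min_snps: int = DEFAULT_MIN_SNPS,
    corrected: bool = False,
    freqs: PopulationFrequencies | None = None,
) -> BlockedFStat:
    """f3(T; A, B) = mean (t-a)(t-b); negative values signal admixture in T."""
    f, cnt = _freq_columns(dataset, (target, a, b), freqs)
    min_count = 1 if corrected else 0
    usable = (cnt[:, 0] > min_count) & (cnt[:, 1] > 0) & (cnt[:, 2] > 0)
    ft, fa, fb = (np.nan_to_num(f[:, i]) for i in range(3))
    num = (ft - fa) * (ft - fb)
    if corrected:
        with np.errstate(divide="ignore", invalid="ignore"):
            num = num - _het_over_n(ft, cnt[:, 0])
    return _blocked_ratio(
        "f3", (target, a, b), num, np.ones_like(num), usable, blocks, min_snps
    )


def _het_over_n(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = p * (1.0 - p) * n / (n - 1.0) / n
    return np.where(n > 1, out, 0.0)


def dstat_batch(
    dataset: GenotypeDataset,
    quadruples: Sequence[tuple[str, str, str, str]],
    blocks: BlockAssignment,
    min_snps: int = DEFAULT_MIN_SNPS,
):
    """Run a batch of D statistics, sharing one frequency tally."""
    import pandas as pd

    pops = sorted({p for quad in quadruples for p in quad})
    freqs = allele_frequencies(dataset, pops)
    rows = []
    for quad in quadruples:
        st = d_statistic(dataset, *quad, blocks=blocks, min_snps=min_snps, freqs=freqs)
        rows.append(
            dict(
                W=quad[0],
                X=quad[1],
                Y=quad[2],
                Z=quad[3],
                D=st.estimate,
                SE=st.se,
                Z_score=st.z,
                n_snps=st.n_snps,
                n_blocks=st.n_blocks,
                below_threshold=st.below_threshold,
            )
        )
    return pd.DataFrame(rows)
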