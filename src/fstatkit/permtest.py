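"""Individual-label permutation tests for D-statistics.

Two schemes validate a population-level D-statistic against the spread that
label swapping produces:

* **Scheme A (exhaustive leave-one)** — designed for an asymmetric contrast
  of a small cohort (e.g. five farmers) against a single anchor individual
  (a lone hunter-gatherer).  Each of the five cohort members takes the
  anchor's slot in turn while the remaining four (plus, optionally, the
  anchor) form the first slot; with the anchor excluded the same enumeration
  yields the within-cohort spread.
* **Scheme B (random split)** — pools two cohorts (e.g. 25 + 5 individuals)
  and redraws the smaller group uniformly at random without replacement,
  a fixed number of times (1000 by default).

The empirical P-value is inclusive of the observed (identity) grouping in
both numerator and denominator: with ``n_perm`` permutations the denominator
is ``n_perm + 1`` and ties (permuted D equal to the observed D) count toward
the numerator, so P is never 0 and its minimum is ``1/(n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .eigendata import GenotypeDataset, allele_frequency_components
from .fstats import BlockAssignment


@dataclass(frozen=True)
class PermutationAssignment:
    group1: tuple[str, ...]
    group2: tuple[str, ...]


def _check_distinct(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate individual id in {what}")


def enumerate_scheme_a(
    group_ids: Sequence[str],
    anchor_id: str,
    include_anchor: bool = True,
    expected_group_size: int | None = 5,
) -> list[PermutationAssignment]:
    """All leave-one-out assignments moving one cohort member into the anchor slot.

    With ``include_anchor`` the anchor individual joins the remaining cohort
    members in group 1; without it, group 1 is the remaining cohort only
    (the within-cohort variant).
    """
    ids = list(group_ids)
    _check_distinct(ids + [anchor_id], "scheme A input")
    if expected_group_size is not None and len(ids) != expected_group_size:
        raise ValueError(
            f"scheme A expects a cohort of {expected_group_size} individuals, got {len(ids)}"
        )
    if len(ids) < 2:
        raise ValueError("scheme A needs at least two cohort individuals")
    assignments = []
    for moved in ids:
        rest = tuple(i for i in ids if i != moved)
        group1 = rest + ((anchor_id,) if include_anchor else ())
        assignments.append(PermutationAssignment(group1=group1, group2=(moved,)))
    return assignments


def sample_scheme_b(
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    expected_sizes: tuple[int, int] | None = (25, 5),
) -> list[PermutationAssignment]:
    """Random re-splits of the pooled individuals preserving group sizes.

    Each permutation draws ``len(group2_ids)`` individuals uniformly without
    replacement from the pooled set into group 2; repeats across permutations
    are allowed (no deduplication), keeping the sampling null exact.
    """
    g1, g2 = list(group1_ids), list(group2_ids)
    _check_distinct(g1 + g2, "scheme B input")
    if expected_sizes is not None and (len(g1), len(g2)) != tuple(expected_sizes):
        raise ValueError(
            f"scheme B expects group sizes {expected_sizes}, got ({len(g1)}, {len(g2)})"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pool = np.array(g1 + g2)
    k = len(g2)
    assignments = []
    for _ in range(n_perm):
        pick = rng.choice(len(pool), size=k, replace=False)
        mask = np.zeros(len(pool), dtype=bool)
        mask[pick] = True
        assignments.append(
            PermutationAssignment(
                group1=tuple(pool[~mask].tolist()), group2=tuple(pool[mask].tolist())
            )
        )
    return assignments


@dataclass
class PermutationResult:
    observed_d: float
    permuted_d: np.ndarray
    n_ge: int  # permutations with D >= observed (ties included)
    n_total: int  # permutations + 1 (identity grouping included)
    identity_inclusive: bool = True
    notes: str = field(
        default="empirical P counts the identity grouping in numerator and denominator"
    )

    @property
    def empirical_p(self) -> float:
        return (1 + self.n_ge) / self.n_total


class _PooledDCalculator:
    """Fast pooled-frequency D for many assignments over a fixed pool.

    Per-individual alt-allele sums and observed-allele counts are tallied
    once; a pseudo-population's frequency is then a column subset sum.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        pool_ids: Sequence[str],
        test_population: str,
        outgroup: str,
    ):
        self.pool_ids = list(pool_ids)
        idx = dataset.indices_of(self.pool_ids)
        alt_cols = []
        cnt_cols = []
        for i in idx:
            alt, cnt = allele_frequency_components(dataset, [i])
            alt_cols.append(alt)
            cnt_cols.append(cnt)
        self.alt = np.column_stack(alt_cols)
        self.cnt = np.column_stack(cnt_cols)
        self.col = {iid: j for j, iid in enumerate(self.pool_ids)}

        from .eigendata import allele_frequencies

        table = allele_frequencies(dataset, [test_population, outgroup])
        fy = table.frequencies[:, 0]
        fz = table.frequencies[:, 1]
        self.yz_ok = (table.allele_counts > 0).all(axis=1)
        self.fy = np.nan_to_num(fy)
        self.fz = np.nan_to_num(fz)

    def d(self, assignment: PermutationAssignment) -> float:
        c1 = [self.col[i] for i in assignment.group1]
        c2 = [self.col[i] for i in assignment.group2]
        n1 = self.cnt[:, c1].sum(axis=1)
        n2 = self.cnt[:, c2].sum(axis=1)
        usable = self.yz_ok & (n1 > 0) & (n2 > 0)
        w = self.alt[usable][:, c1].sum(axis=1) / n1[usable]
        x = self.alt[usable][:, c2].sum(axis=1) / n2[usable]
        y = self.fy[usable]
        z = self.fz[usable]
        num = ((w - x) * (y - z)).sum()
        den = ((w + x - 2 * w * x) * (y + z - 2 * y * z)).sum()
        if den == 0:
            raise ZeroDivisionError("degenerate D in permutation: zero denominator")
        return float(num / den)


def permutation_test(
    dataset: GenotypeDataset,
    observed_group1: Sequence[str],
    observed_group2: Sequence[str],
    assignments: Sequence[PermutationAssignment],
    test_population: str,
    outgroup: str,
    blocks: BlockAssignment | None = None,
) -> PermutationResult:
    """Empirical P for D(group1, group2; test, outgroup) under label permutation.

    The observed statistic uses the given grouping; each assignment re-pools
    the individuals into pseudo-populations and recomputes D on its own set of
    usable sites.  ``blocks`` is accepted for interface symmetry (jackknife
    SEs play no role in the empirical P-value).
    """
    pool = list(observed_group1) + list(observed_group2)
    for a in assignments:
        extra = (set(a.group1) | set(a.group2)) - set(pool)
        if extra:
            raise ValueError(f"assignment references ids outside the pool: {sorted(extra)}")
    calc = _PooledDCalculator(dataset, pool, test_population, outgroup)
    observed = calc.d(
        PermutationAssignment(tuple(observed_group1), tuple(observed_group2))
    )
    permuted = np.array([calc.d(a) for a in assignments])
    n_ge = int((permuted >= observed).sum())
    return PermutationResult(
        observed_d=observed,
        permuted_d=permuted,
        n_ge=n_ge,
        n_total=len(assignments) + 1,
    )
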