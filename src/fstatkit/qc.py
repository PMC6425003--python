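"""Sample-level quality control: coverage-based sex typing and pairwise
mismatch rates for relatedness screening.

Genetic sex is called from the X- and Y-chromosome coverages normalized by the
autosomal mean.  The default thresholds follow common shotgun sex-typing
practice (males: normalized Y >= 0.3 with normalized X <= 0.8; females:
normalized Y <= 0.1 with normalized X >= 0.8); anything in the gap is left
unassigned.  The contract is the ratio computation — the cutoffs are
configurable.

Relatedness screening uses the plain pairwise mismatch fraction over sites
non-missing in both individuals of a pair.  Because the expected baseline
depends on population diversity and on pseudo-haploid sampling noise, pairs
are judged relative to the distribution of within-population rates (z-scores
against the population mean), not against an absolute cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .eigendata import MISSING, GenotypeDataset


@dataclass(frozen=True)
class SexThresholds:
    y_male_min: float = 0.3
    x_male_max: float = 0.8
    y_female_max: float = 0.1
    x_female_min: float = 0.8


@dataclass(frozen=True)
class SexCall:
    individual_id: str
    sex: str  # "male" | "female" | "unassigned"
    x_rate: float
    y_rate: float


def genetic_sex(
    individual_id: str,
    autosomal_coverage: float,
    x_coverage: float,
    y_coverage: float,
    thresholds: SexThresholds = SexThresholds(),
) -> SexCall:
    """Call genetic sex from mean coverages of the autosomes, X and Y."""
    if autosomal_coverage <= 0:
        raise ValueError(
            f"{individual_id}: autosomal coverage must be positive to normalize"
        )
    if min(x_coverage, y_coverage) < 0:
        raise ValueError(f"{individual_id}: coverages must be non-negative")
    x_rate = x_coverage / autosomal_coverage
    y_rate = y_coverage / autosomal_coverage
    if y_rate >= thresholds.y_male_min and x_rate <= thresholds.x_male_max:
        sex = "male"
    elif y_rate <= thresholds.y_female_max and x_rate >= thresholds.x_female_min:
        sex = "female"
    else:
        sex = "unassigned"
    return SexCall(individual_id, sex, x_rate, y_rate)


def genetic_sex_table(
    coverage: pd.DataFrame, thresholds: SexThresholds = SexThresholds()
) -> pd.DataFrame:
    """Vectorized :func:`genetic_sex` over a coverage table.

    Expects columns ``individual_id, autosomal, X, Y`` (fold coverage).
    """
    calls = [
        genetic_sex(r.individual_id, r.autosomal, r.X, r.Y, thresholds)
        for r in coverage.itertuples(index=False)
    ]
    return pd.DataFrame(
        dict(
            individual_id=[c.individual_id for c in calls],
            x_rate=[c.x_rate for c in calls],
            y_rate=[c.y_rate for c in calls],
            sex=[c.sex for c in calls],
        )
    )


@dataclass(frozen=True)
class MismatchResult:
    individual_1: str
    individual_2: str
    n_overlap: int
    n_mismatch: int

    @property
    def rate(self) -> float:
        return self.n_mismatch / self.n_overlap if self.n_overlap > 0 else float("nan")

    @property
    def defined(self) -> bool:
        return self.n_overlap > 0


def pairwise_mismatch(
    dataset: GenotypeDataset,
    pairs: Iterable[tuple[str, str]] | None = None,
    individual_ids: Sequence[str] | None = None,
) -> list[MismatchResult]:
    """Mismatch rate per pair over sites non-missing in both individuals.

    With neither ``pairs`` nor ``individual_ids`` given, all pairs in the
    dataset are compared.
    """
    if pairs is None:
        ids = list(individual_ids) if individual_ids is not None else dataset.individual_ids
        pairs = itertools.combinations(ids, 2)
    results = []
    for id1, id2 in pairs:
        i = dataset.indices_of([id1])[0]
        j = dataset.indices_of([id2])[0]
        gi = dataset.genotypes[:, i]
        gj = dataset.genotypes[:, j]
        both = (gi != MISSING) & (gj != MISSING)
        n_overlap = int(both.sum())
        n_mismatch = int((gi[both] != gj[both]).sum())
        results.append(MismatchResult(id1, id2, n_overlap, n_mismatch))
    return results


def mismatch_table(results: Sequence[MismatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            individual_1=[r.individual_1 for r in results],
            individual_2=[r.individual_2 for r in results],
            n_overlap=[r.n_overlap for r in results],
            n_mismatch=[r.n_mismatch for r in results],
            mismatch_rate=[r.rate for r in results],
            defined=[r.defined for r in results],
        )
    )


def relatedness_zscores(
    results: Sequence[MismatchResult], population_of: dict[str, str]
) -> pd.DataFrame:
    """Z-score of each within-population pair against its population baseline.

    Negative z-scores flag pairs with unusually low mismatch (potential close
    relatives); pairs spanning two populations are ignored.
    """
    rows = []
    by_pop: dict[str, list[MismatchResult]] = {}
    for r in results:
        if not r.defined:
            continue
        p1 = population_of.get(r.individual_1)
        p2 = population_of.get(r.individual_2)
        if p1 is not None and p1 == p2:
            by_pop.setdefault(p1, []).append(r)
    for pop, members in by_pop.items():
        rates = np.array([m.rate for m in members])
        mu = rates.mean()
        sd = rates.std(ddof=1) if len(rates) > 1 else float("nan")
        for m, rate in zip(members, rates):
            rows.append(
                dict(
                    population=pop,
                    individual_1=m.individual_1,
                    individual_2=m.individual_2,
                    mismatch_rate=rate,
                    population_mean=mu,
                    zscore=(rate - mu) / sd if sd and sd > 0 else float("nan"),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "individual_1",
            "individual_2",
            "mismatch_rate",
            "population_mean",
            "zscore",
        ],
    )
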