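"""Independent oracles used by the test suite.

Everything here is deliberately written as a separate, simple-minded code
path (plain Python loops, textbook formulas) so it can cross-check the
vectorized implementations without sharing code with them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from fstatkit.eigendata import MISSING, GenotypeDataset


def site_frequency(dataset: GenotypeDataset, population: str, site: int) -> tuple[float, int]:
    """Brute-force alt-allele frequency and allele count at one site."""
    alt = 0.0
    count = 0
    for j, ind in enumerate(dataset.individuals):
        if ind.population_label != population:
            continue
        g = int(dataset.genotypes[site, j])
        if g == MISSING:
            continue
        if dataset.pseudo_haploid[j]:
            alt += g / 2
            count += 1
        else:
            alt += g
            count += 2
    return (alt / count if count else float("nan")), count


def brute_force_stat(dataset: GenotypeDataset, kind: str, pops: tuple[str, ...]) -> float:
    """Per-site tally of D/f4/f3/f2 with explicit loops (the oracle)."""
    num_sum = 0.0
    den_sum = 0.0
    n_used = 0
    for s in range(dataset.n_snps):
        freqs = []
        ok = True
        for p in pops:
            f, c = site_frequency(dataset, p, s)
            if c == 0:
                ok = False
                break
            freqs.append(f)
        if not ok:
            continue
        n_used += 1
        if kind == "D":
            w, x, y, z = freqs
            num_sum += (w - x) * (y - z)
            den_sum += (w + x - 2 * w * x) * (y + z - 2 * y * z)
        elif kind == "f4":
            a, b, c, d = freqs
            num_sum += (a - b) * (c - d)
        elif kind == "f3":
            t, a, b = freqs
            num_sum += (t - a) * (t - b)
        elif kind == "f2":
            a, b = freqs
            num_sum += (a - b) ** 2
        else:
            raise ValueError(kind)
    if kind == "D":
        return num_sum / den_sum
    return num_sum / n_used


def textbook_jackknife(theta_full: float, theta_loo: np.ndarray) -> float:
    """Unweighted delete-one jackknife SE (equal-weight closed form)."""
    g = len(theta_loo)
    mean_loo = theta_loo.mean()
    var = (g - 1) / g * ((theta_loo - mean_loo) ** 2).sum()
    return math.sqrt(var)


def brute_force_d_for_groups(
    dataset: GenotypeDataset,
    group1: tuple[str, ...],
    group2: tuple[str, ...],
    test_pop: str,
    outgroup: str,
) -> float:
    """D with explicit pooled-individual frequencies (permutation oracle)."""
    idx1 = [dataset.individual_ids.index(i) for i in group1]
    idx2 = [dataset.individual_ids.index(i) for i in group2]
    num_sum = den_sum = 0.0
    for s in range(dataset.n_snps):
        fy, cy = site_frequency(dataset, test_pop, s)
        fz, cz = site_frequency(dataset, outgroup, s)
        if cy == 0 or cz == 0:
            continue
        pooled = []
        ok = True
        for idx in (idx1, idx2):
            alt = 0.0
            cnt = 0
            for j in idx:
                g = int(dataset.genotypes[s, j])
                if g == MISSING:
                    continue
                if dataset.pseudo_haploid[j]:
                    alt += g / 2
                    cnt += 1
                else:
                    alt += g
                    cnt += 2
            if cnt == 0:
                ok = False
                break
            pooled.append(alt / cnt)
        if not ok:
            continue
        w, x = pooled
        num_sum += (w - x) * (fy - fz)
        den_sum += (w + x - 2 * w * x) * (fy + fz - 2 * fy * fz)
    return num_sum / den_sum
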