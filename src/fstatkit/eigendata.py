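"""Genotype data model, EIGENSTRAT text I/O, pseudo-haploid calling, merging.

Internal genotype convention
----------------------------
Genotypes are stored as **ALT-allele counts** in ``{0, 1, 2}`` with ``-1`` for
missing data.  The EIGENSTRAT ``.geno`` text format counts copies of the
*reference* allele, so values are flipped (``alt = 2 - ref_count``) when
reading and flipped back when writing.  Keeping a single internal convention
avoids sign errors in downstream f-statistics.

Pseudo-haploid individuals carry a single sampled allele per site, coded as a
homozygous genotype (0 or 2, never 1).  For allele-frequency estimation such a
genotype contributes **one** allele observation, not two: the 0/2 coding is a
notational device for a haploid draw, and double-counting it would understate
the sampling variance of the frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

_VALID_SEX = frozenset("MFU")
_AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class EigenstratFormatError(ValueError):
    """Malformed EIGENSTRAT input (dimension mismatch, illegal characters...)."""


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic site of the capture panel.

    ``genetic_position`` is in morgans and may be 0 when no genetic map is
    available; ``physical_position`` is 1-based.
    """

    snp_id: str
    chromosome: str
    genetic_position: float
    physical_position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.physical_position <= 0:
            raise ValueError(
                f"SNP {self.snp_id}: physical position must be positive, "
                f"got {self.physical_position}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref and alt alleles are identical")

    @property
    def is_strand_ambiguous(self) -> bool:
        return (self.ref_allele, self.alt_allele) in _AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    sex: str
    population_label: str

    def __post_init__(self) -> None:
        if self.sex not in _VALID_SEX:
            raise ValueError(
                f"individual {self.individual_id}: sex must be one of M/F/U, got {self.sex!r}"
            )


@dataclass(frozen=True)
class PileupSite:
    """High-quality base counts observed at one targeted SNP.

    Only bases passing the caller's quality threshold belong here; quality
    filtering happens upstream of :func:`pseudohaploid_call`.
    """

    snp: SNPRecord
    base_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for base, count in self.base_counts.items():
            if count < 0:
                raise ValueError(f"negative base count for {base!r} at {self.snp.snp_id}")


@dataclass
class GenotypeDataset:
    """SNP-by-individual matrix of ALT-allele counts with population labels."""

    snps: list[SNPRecord]
    individuals: list[IndividualRecord]
    genotypes: np.ndarray  # (n_snps, n_individuals) int8, MISSING = -1
    pseudo_haploid: np.ndarray = field(default=None)  # (n_individuals,) bool

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.pseudo_haploid is None:
            self.pseudo_haploid = np.zeros(len(self.individuals), dtype=bool)
        self.pseudo_haploid = np.asarray(self.pseudo_haploid, dtype=bool)
        if self.genotypes.shape != (len(self.snps), len(self.individuals)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.individuals)} individuals"
            )
        if self.pseudo_haploid.shape != (len(self.individuals),):
            raise ValueError("pseudo_haploid flag vector has wrong length")
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in dataset")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {-1, 0, 1, 2}")
        if self.pseudo_haploid.any():
            het = self.genotypes[:, self.pseudo_haploid] == 1
            if het.any():
                raise ValueError("pseudo-haploid individuals may not carry heterozygous calls")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: dict[str, int] = {}
        prev_chrom = None
        prev_pos = -1
        for i, snp in enumerate(self.snps):
            if snp.chromosome != prev_chrom:
                if snp.chromosome in seen:
                    raise ValueError(
                        f"chromosome {snp.chromosome} appears in non-contiguous runs"
                    )
                seen[snp.chromosome] = i
                prev_chrom = snp.chromosome
                prev_pos = -1
            if snp.physical_position < prev_pos:
                raise ValueError(
                    f"SNPs not sorted by position within chromosome {snp.chromosome} "
                    f"(index {i})"
                )
            prev_pos = snp.physical_position

    # -- basic introspection -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def population_labels(self) -> list[str]:
        return [ind.population_label for ind in self.individuals]

    def population_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.population_labels) == label)
        if idx.size == 0:
            raise KeyError(f"population {label!r} not present in dataset")
        return idx

    def indices_of(self, individual_ids: Sequence[str]) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in individual_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not present in dataset") from None

    def subset(
        self,
        snp_indices: Sequence[int] | None = None,
        individual_indices: Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_snps) if snp_indices is None else np.asarray(snp_indices)
        ii = (
            np.arange(self.n_individuals)
            if individual_indices is None
            else np.asarray(individual_indices)
        )
        return GenotypeDataset(
            snps=[self.snps[i] for i in si],
            individuals=[self.individuals[i] for i in ii],
            genotypes=self.genotypes[np.ix_(si, ii)].copy(),
            pseudo_haploid=self.pseudo_haploid[ii].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.individuals == other.individuals
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.pseudo_haploid, other.pseudo_haploid)
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------


def _format_gpos(g: float) -> str:
    return format(g, ".6f").rstrip("0").rstrip(".") if g else "0"


def read_eigenstrat(
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
    pseudo_haploid: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read an EIGENSTRAT (text) triplet into a :class:`GenotypeDataset`.

    ``pseudo_haploid`` optionally names individuals whose genotypes are
    single-allele draws; the format itself does not record this.
    """
    snps: list[SNPRecord] = []
    for lineno, line in enumerate(Path(snp_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise EigenstratFormatError(
                f"{snp_path}:{lineno}: expected 6 columns in .snp file, got {len(parts)}"
            )
        snps.append(
            SNPRecord(
                snp_id=parts[0],
                chromosome=parts[1],
                genetic_position=float(parts[2]),
                physical_position=int(parts[3]),
                ref_allele=parts[4],
                alt_allele=parts[5],
            )
        )

    individuals: list[IndividualRecord] = []
    for lineno, line in enumerate(Path(ind_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise EigenstratFormatError(
                f"{ind_path}:{lineno}: expected 3 columns in .ind file, got {len(parts)}"
            )
        individuals.append(
            IndividualRecord(individual_id=parts[0], sex=parts[1], population_label=parts[2])
        )

    n_ind = len(individuals)
    decode = np.full(128, -2, dtype=np.int8)
    # EIGENSTRAT digit = reference-allele count; internal value = alt count.
    decode[ord("0")] = 2
    decode[ord("1")] = 1
    decode[ord("2")] = 0
    decode[ord("9")] = MISSING

    rows: list[np.ndarray] = []
    geno_lines = Path(geno_path).read_text().splitlines()
    body = [ln for ln in geno_lines if ln.strip()]
    if len(body) != len(snps):
        raise EigenstratFormatError(
            f"{geno_path}: {len(body)} genotype lines for {len(snps)} SNPs in {snp_path}"
        )
    for lineno, line in enumerate(body, 1):
        if len(line) != n_ind:
            raise EigenstratFormatError(
                f"{geno_path}:{lineno}: line has {len(line)} characters for "
                f"{n_ind} declared individuals"
            )
        row = decode[np.frombuffer(line.encode("ascii"), dtype=np.uint8)]
        if (row == -2).any():
            bad = line[int(np.flatnonzero(row == -2)[0])]
            raise EigenstratFormatError(
                f"{geno_path}:{lineno}: illegal genotype character {bad!r}"
            )
        rows.append(row)

    genotypes = (
        np.vstack(rows) if rows else np.empty((0, n_ind), dtype=np.int8)
    )
    ph = np.zeros(n_ind, dtype=bool)
    if pseudo_haploid:
        wanted = set(pseudo_haploid)
        for i, ind in enumerate(individuals):
            if ind.individual_id in wanted:
                ph[i] = True
    return GenotypeDataset(snps, individuals, genotypes, ph)


def write_eigenstrat(
    dataset: GenotypeDataset,
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
) -> None:
    """Write a dataset as an EIGENSTRAT text triplet (lossless round-trip)."""
    encode = np.array(["?"] * 3 + ["9"], dtype="U1")
    # index by alt count; MISSING (-1) wraps to the last slot
    encode[0], encode[1], encode[2] = "2", "1", "0"

    with open(geno_path, "w") as fh:
        for row in dataset.genotypes:
            fh.write("".join(encode[row]) + "\n")
    with open(snp_path, "w") as fh:
        for s in dataset.snps:
            fh.write(
                f"{s.snp_id}\t{s.chromosome}\t{_format_gpos(s.genetic_position)}"
                f"\t{s.physical_position}\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for ind in dataset.individuals:
            fh.write(f"{ind.individual_id}\t{ind.sex}\t{ind.population_label}\n")


# ---------------------------------------------------------------------------
# Pseudo-haploid calling
# ---------------------------------------------------------------------------


def pseudohaploid_call(
    sites: Sequence[PileupSite],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Random single-allele genotype calls from per-site base counts.

    One base is drawn uniformly among the counted (already quality-filtered)
    bases at each site; the genotype is 0 if it matches the reference allele,
    2 if it matches the alternative, and missing otherwise (including empty
    pileups and bases matching neither allele).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.full(len(sites), MISSING, dtype=np.int8)
    for i, site in enumerate(sites):
        bases = [b for b, c in site.base_counts.items() if c > 0]
        if not bases:
            continue
        counts = np.array([site.base_counts[b] for b in bases], dtype=float)
        drawn = bases[rng.choice(len(bases), p=counts / counts.sum())]
        if drawn == site.snp.ref_allele:
            out[i] = 0
        elif drawn == site.snp.alt_allele:
            out[i] = 2
    return out


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


class MergeResult(NamedTuple):
    dataset: GenotypeDataset
    log: pd.DataFrame  # columns: snp_id, chromosome, position, action, detail


def merge_datasets(
    a: GenotypeDataset,
    b: GenotypeDataset,
    drop_strand_ambiguous: bool = False,
) -> MergeResult:
    """Merge two datasets on the intersection of (chromosome, position).

    Allele pairs are reconciled: when one input codes the site with ref/alt
    exchanged, its genotypes are flipped (g -> 2-g).  Sites whose allele pairs
    are incompatible are dropped and logged.  The merged allele order is
    canonicalized (lexicographically smaller allele as reference) so that the
    merge is symmetric in its arguments.
    """
    dup = set(a.individual_ids) & set(b.individual_ids)
    if dup:
        raise ValueError(f"duplicate individual ids across datasets: {sorted(dup)}")

    index_b = {(s.chromosome, s.physical_position): i for i, s in enumerate(b.snps)}
    kept_snps: list[SNPRecord] = []
    rows_a: list[int] = []
    rows_b: list[int] = []
    flip_a: list[bool] = []
    flip_b: list[bool] = []
    log_rows: list[dict] = []

    for ia, snp_a in enumerate(a.snps):
        key = (snp_a.chromosome, snp_a.physical_position)
        ib = index_b.get(key)
        if ib is None:
            continue
        snp_b = b.snps[ib]
        pair_a = (snp_a.ref_allele, snp_a.alt_allele)
        pair_b = (snp_b.ref_allele, snp_b.alt_allele)
        if set(pair_a) != set(pair_b):
            log_rows.append(
                dict(
                    snp_id=snp_a.snp_id,
                    chromosome=snp_a.chromosome,
                    position=snp_a.physical_position,
                    action="dropped",
                    detail=f"incompatible alleles {pair_a} vs {pair_b}",
                )
            )
            continue
        if drop_strand_ambiguous and snp_a.is_strand_ambiguous:
            log_rows.append(
                dict(
                    snp_id=snp_a.snp_id,
                    chromosome=snp_a.chromosome,
                    position=snp_a.physical_position,
                    action="dropped",
                    detail=f"strand-ambiguous pair {pair_a}",
                )
            )
            continue
        ref, alt = sorted(pair_a)
        kept_snps.append(replace(snp_a, ref_allele=ref, alt_allele=alt))
        rows_a.append(ia)
        rows_b.append(ib)
        flip_a.append(pair_a != (ref, alt))
        flip_b.append(pair_b != (ref, alt))

    ga = a.genotypes[rows_a, :].copy()
    gb = b.genotypes[rows_b, :].copy()
    for g, flips in ((ga, flip_a), (gb, flip_b)):
        fl = np.asarray(flips, dtype=bool)
        if fl.any():
            sub = g[fl, :]
            nonmiss = sub != MISSING
            sub[nonmiss] = 2 - sub[nonmiss]
            g[fl, :] = sub

    merged = GenotypeDataset(
        snps=kept_snps,
        individuals=list(a.individuals) + list(b.individuals),
        genotypes=(
            np.hstack([ga, gb])
            if kept_snps
            else np.empty((0, a.n_individuals + b.n_individuals), dtype=np.int8)
        ),
        pseudo_haploid=np.concatenate([a.pseudo_haploid, b.pseudo_haploid]),
    )
    log = pd.DataFrame(
        log_rows, columns=["snp_id", "chromosome", "position", "action", "detail"]
    )
    return MergeResult(merged, log)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequency_components(
    dataset: GenotypeDataset, individual_indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt-allele sum, observed allele count) for a pool of individuals.

    Diploid genotypes contribute their alt count over 2 alleles; pseudo-haploid
    genotypes contribute alt/2 over 1 allele.
    """
    idx = np.asarray(individual_indices, dtype=int)
    g = dataset.genotypes[:, idx].astype(np.float64)
    ph = dataset.pseudo_haploid[idx]
    observed = g >= 0
    g[~observed] = 0.0
    alt = np.where(ph[None, :], g / 2.0, g)
    nallele = observed * np.where(ph[None, :], 1.0, 2.0)
    return alt.sum(axis=1), nallele.sum(axis=1)


@dataclass
class PopulationFrequencies:
    """Per-population alt-allele frequencies with observed allele counts.

    ``frequencies`` is NaN where a population has no observed alleles at a
    site; ``allele_counts`` is 0 there.
    """

    populations: list[str]
    frequencies: np.ndarray  # (n_snps, n_pops) float, NaN where absent
    allele_counts: np.ndarray  # (n_snps, n_pops) float

    def column(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise KeyError(f"population {label!r} not in frequency table") from None


def allele_frequencies(
    dataset: GenotypeDataset, population_labels: Sequence[str]
) -> PopulationFrequencies:
    """Alt-allele frequency and allele count per SNP for the named populations."""
    pops = list(dict.fromkeys(population_labels))
    freqs = np.empty((dataset.n_snps, len(pops)))
    counts = np.empty((dataset.n_snps, len(pops)))
    for j, label in enumerate(pops):
        idx = dataset.population_indices(label)  # raises KeyError if unknown
        alt, n = allele_frequency_components(dataset, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, j] = np.where(n > 0, alt / np.where(n > 0, n, 1.0), np.nan)
        counts[:, j] = n
    return PopulationFrequencies(pops, freqs, counts)
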