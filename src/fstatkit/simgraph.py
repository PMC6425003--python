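"""Admixture-graph allele-frequency simulation with pseudo-haploid sampling.

The generator produces exactly the statistical structure the inference stack
consumes: biallelic SNP frequencies evolving on a rooted admixture graph with
per-edge Balding–Nichols drift, small per-population cohorts of diploid or
pseudo-haploid individuals, and coverage-driven missingness.

Model
-----
* Root frequencies per SNP ~ Uniform(0.05, 0.95) by default (truncation keeps
  fixation from dominating small-drift edges).
* Along a drift edge with parameter ``F`` in [0, 1), the child frequency is
  Beta-distributed with mean equal to the parent frequency ``p`` and variance
  ``p (1 - p) F``; ``F = 0`` copies.  Frequencies at 0 or 1 stay fixed.
* An admixture node's frequency is the mixture ``lam * parentA + (1 - lam) *
  parentB`` per SNP; multi-way mixtures are chains of two-parent events.
* Diploid genotypes ~ Binomial(2, p); pseudo-haploid individuals carry one
  allele drawn from the diploid pair, coded 0/2.  Per-site missingness is
  Bernoulli with rate ``exp(-coverage)``, the zero-read probability of a
  Poisson read-count model, matching the sub-1x to ~3x regime of 1240k-capture
  ancient genomes.

The registered scenarios mirror the study design this package reproduces:
single-digit cohorts of low-coverage pseudo-haploid ancient genomes set
against well-sampled modern outgroup panels, with mixture proportions fixed
at the published point estimates so recovery can be scored against a known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .eigendata import MISSING, GenotypeDataset, IndividualRecord, SNPRecord


@dataclass(frozen=True)
class DriftEdge:
    parent: str
    child: str
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"drift parameter must be in [0, 1), got {self.f}")


@dataclass(frozen=True)
class AdmixtureEvent:
    child: str
    parent_a: str
    parent_b: str
    prop_a: float  # mixing proportion lambda on parent_a

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_a <= 1.0:
            raise ValueError(f"mixing proportion must be in [0, 1], got {self.prop_a}")


@dataclass
class AdmixtureGraph:
    """Rooted acyclic graph: drift edges (1 parent) and admixture nodes (2)."""

    root: str
    drift_edges: list[DriftEdge]
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._order = self._toposort()

    @property
    def nodes(self) -> list[str]:
        return list(self._order)

    @property
    def leaves(self) -> list[str]:
        parents = {e.parent for e in self.drift_edges}
        parents |= {a.parent_a for a in self.admixture_events}
        parents |= {a.parent_b for a in self.admixture_events}
        return [n for n in self._order if n not in parents]

    def _toposort(self) -> list[str]:
        parents: dict[str, tuple[str, ...]] = {}
        for e in self.drift_edges:
            if e.child in parents or e.child == self.root:
                raise ValueError(f"node {e.child!r} has multiple parent definitions")
            parents[e.child] = (e.parent,)
        for a in self.admixture_events:
            if a.child in parents or a.child == self.root:
                raise ValueError(f"node {a.child!r} has multiple parent definitions")
            parents[a.child] = (a.parent_a, a.parent_b)
        order = [self.root]
        placed = {self.root}
        pending = dict(parents)
        while pending:
            ready = [c for c, ps in pending.items() if all(p in placed for p in ps)]
            if not ready:
                raise ValueError(
                    f"graph is cyclic or disconnected around nodes {sorted(pending)}"
                )
            for c in sorted(ready):
                order.append(c)
                placed.add(c)
                del pending[c]
        return order


@dataclass(frozen=True)
class PopulationSample:
    """Sampling plan for one leaf population."""

    n: int
    coverage: float | tuple[float, ...]
    pseudo_haploid: bool = True

    def coverages(self) -> np.ndarray:
        cov = (
            np.full(self.n, self.coverage, dtype=float)
            if np.isscalar(self.coverage)
            else np.asarray(self.coverage, dtype=float)
        )
        if cov.shape != (self.n,):
            raise ValueError(f"coverage list length {cov.shape} does not match n={self.n}")
        if (cov < 0).any():
            raise ValueError("coverages must be non-negative")
        return cov


@dataclass
class SimulationConfig:
    n_snps: int
    samples: dict[str, PopulationSample]
    seed: int | None = None
    root_freq_range: tuple[float, float] = (0.05, 0.95)
    n_chromosomes: int = 22
    snp_spacing_bp: int = 28_000  # ~1.2M-panel density scaled to n_snps
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for pop, plan in self.samples.items():
            if plan.n < 1:
                raise ValueError(f"sample size for {pop} must be >= 1")


def simulate_frequencies(
    graph: AdmixtureGraph,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> dict[str, np.ndarray]:
    """Per-node allele frequency arrays (one entry per SNP) for all nodes."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        rng if rng is not None else config.seed
    )
    lo, hi = config.root_freq_range
    freqs: dict[str, np.ndarray] = {
        graph.root: rng.uniform(lo, hi, size=config.n_snps)
    }
    drift_by_child = {e.child: e for e in graph.drift_edges}
    admix_by_child = {a.child: a for a in graph.admixture_events}
    for node in graph.nodes:
        if node == graph.root:
            continue
        if node in drift_by_child:
            e = drift_by_child[node]
            freqs[node] = _drift(freqs[e.parent], e.f, rng)
        else:
            a = admix_by_child[node]
            freqs[node] = a.prop_a * freqs[a.parent_a] + (1 - a.prop_a) * freqs[a.parent_b]
    return freqs


def _drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols transition: Beta with mean p and variance p(1-p)F."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    interior = (p > 0.0) & (p < 1.0)
    out = p.copy()
    if interior.any():
        pi = p[interior]
        out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def _snp_panel(config: SimulationConfig) -> list[SNPRecord]:
    per = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per[: config.n_snps % config.n_chromosomes] += 1
    snps = []
    i = 0
    for c in range(config.n_chromosomes):
        for j in range(per[c]):
            pos = (j + 1) * config.snp_spacing_bp
            snps.append(
                SNPRecord(
                    snp_id=f"snp{i}",
                    chromosome=str(c + 1),
                    genetic_position=pos * config.cm_per_mb * 1e-8,
                    physical_position=pos,
                    ref_allele="A",
                    alt_allele="G",
                )
            )
            i += 1
    return snps


def sample_genotypes(
    frequencies: Mapping[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> GenotypeDataset:
    """Draw a genotype dataset from per-leaf frequencies under the sampling plan."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        rng if rng is not None else config.seed
    )
    snps = _snp_panel(config)
    individuals: list[IndividualRecord] = []
    columns: list[np.ndarray] = []
    ph_flags: list[bool] = []
    for pop, plan in config.samples.items():
        p = np.asarray(frequencies[pop], dtype=float)
        if p.shape != (config.n_snps,):
            raise ValueError(f"frequency array for {pop} has shape {p.shape}")
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"frequencies for {pop} outside [0, 1]")
        covs = plan.coverages()
        for i in range(plan.n):
            g = rng.binomial(2, p).astype(np.int8)
            if plan.pseudo_haploid:
                het = g == 1
                g[het] = 2 * rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
            p_miss = np.exp(-covs[i])
            if p_miss > 0:
                g[rng.random(config.n_snps) < p_miss] = MISSING
            columns.append(g)
            ph_flags.append(plan.pseudo_haploid)
            individuals.append(
                IndividualRecord(
                    individual_id=f"{pop}_{i}", sex="U", population_label=pop
                )
            )
    genotypes = (
        np.column_stack(columns)
        if columns
        else np.empty((config.n_snps, 0), dtype=np.int8)
    )
    return GenotypeDataset(snps, individuals, genotypes, np.array(ph_flags, dtype=bool))


def simulate_dataset(
    graph: AdmixtureGraph,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> GenotypeDataset:
    """Frequencies + genotype sampling in one step with a single RNG stream."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        rng if rng is not None else config.seed
    )
    freqs = simulate_frequencies(graph, config, rng)
    return sample_genotypes(freqs, config, rng)


# ---------------------------------------------------------------------------
# Registered study scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpAdmModelSpec:
    target: str
    sources: tuple[str, ...]
    outgroups: tuple[str, ...]
    true_weights: tuple[float, ...]


@dataclass
class Scenario:
    name: str
    graph: AdmixtureGraph
    config: SimulationConfig
    models: list[QpAdmModelSpec]
    description: str

    def with_seed(self, seed: int) -> "Scenario":
        return Scenario(
            self.name,
            self.graph,
            replace(self.config, seed=seed),
            self.models,
            self.description,
        )


SCENARIO_NAMES = (
    "aaf_two_way",
    "acf_two_way",
    "irongates_three_way",
    "basal_eurasian",
)

_MODERN = dict(n=10, coverage=30.0, pseudo_haploid=False)


def _backbone() -> list[DriftEdge]:
    """Out-of-Africa backbone shared by the Anatolian scenarios."""
    return [
        DriftEdge("Root", "Mbuti", 0.10),
        DriftEdge("Root", "NonAfr", 0.05),
        DriftEdge("NonAfr", "East", 0.02),
        DriftEdge("East", "Han", 0.03),
        DriftEdge("East", "Onge", 0.04),
        DriftEdge("NonAfr", "West", 0.02),
        DriftEdge("West", "Kostenki14", 0.045),
        DriftEdge("West", "West2", 0.01),
    ]


def study_scenario(name: str, n_snps: int = 100_000, seed: int | None = None) -> Scenario:
    """Preconfigured admixture-graph scenarios with known true proportions.

    The true mixing proportions are set to the published point estimates of
    the study designs they emulate: a two-way hunter-gatherer + Iranian
    Neolithic model for the Aceramic farmers (0.897/0.103), a two-way Aceramic
    + Levantine model for the Ceramic farmers (0.787/0.213), a three-way
    Near-East + WHG + EHG model for the Iron Gates hunter-gatherers
    (0.258/0.629/0.113) and a Basal Eurasian configuration with alpha 0.248
    (AHG analog) and 0.385 (Natufian analog).  Cohort sizes and coverages
    mirror the study's regime (one 2.9x hunter-gatherer, five sub-1.5x
    farmers, 25 later farmers, modern diploid outgroup panels).
    """
    if name == "aaf_two_way":
        lam = 0.897
        graph = AdmixtureGraph(
            root="Root",
            drift_edges=_backbone()
            + [
                DriftEdge("West2", "NE", 0.015),
                DriftEdge("NE", "AnatB", 0.08),
                DriftEdge("NE", "IranB", 0.08),
                DriftEdge("AnatB", "AHGanc", 0.012),
                DriftEdge("AHGanc", "AHG", 0.015),
                DriftEdge("AnatB", "LevB", 0.008),
                DriftEdge("LevB", "Levant_N", 0.02),
                DriftEdge("IranB", "CHG", 0.015),
                DriftEdge("IranB", "IranAnc", 0.008),
                DriftEdge("IranAnc", "Iran_N", 0.012),
                DriftEdge("AAFmix", "AAF", 0.008),
            ],
            admixture_events=[AdmixtureEvent("AAFmix", "AHGanc", "IranAnc", lam)],
        )
        samples = {
            "Mbuti": PopulationSample(**_MODERN),
            "Han": PopulationSample(**_MODERN),
            "Onge": PopulationSample(**_MODERN),
            "Kostenki14": PopulationSample(1, 2.5),
            "Levant_N": PopulationSample(2, (0.16, 0.75)),
            "CHG": PopulationSample(2, 5.0),
            "AHG": PopulationSample(1, 2.9),
            "Iran_N": PopulationSample(5, 1.0),
            "AAF": PopulationSample(5, (1.48, 0.8, 0.9, 0.76, 0.69)),
        }
        models = [
            QpAdmModelSpec(
                target="AAF",
                sources=("AHG", "Iran_N"),
                outgroups=("Mbuti", "Han", "Onge", "Kostenki14", "Levant_N", "CHG"),
                true_weights=(lam, 1 - lam),
            )
        ]
        description = (
            "Aceramic farmers as a two-way mixture of the local hunter-gatherer "
            "lineage (89.7%) and an Iranian-Neolithic-related one (10.3%)."
        )
    elif name == "acf_two_way":
        lam = 0.787
        graph = AdmixtureGraph(
            root="Root",
            drift_edges=_backbone()
            + [
                DriftEdge("West2", "NE", 0.015),
                DriftEdge("NE", "AnatB", 0.06),
                DriftEdge("NE", "IranB", 0.04),
                DriftEdge("IranB", "CHG", 0.015),
                DriftEdge("AnatB", "AAFanc", 0.012),
                DriftEdge("AAFanc", "AAF", 0.012),
                DriftEdge("NE", "LevB", 0.06),
                DriftEdge("LevB", "Natufian", 0.015),
                DriftEdge("LevB", "LevAnc", 0.008),
                DriftEdge("LevAnc", "Levant_N", 0.012),
                DriftEdge("ACFmix", "ACF", 0.006),
            ],
            admixture_events=[AdmixtureEvent("ACFmix", "AAFanc", "LevAnc", lam)],
        )
        samples = {
            "Mbuti": PopulationSample(**_MODERN),
            "Han": PopulationSample(**_MODERN),
            "Onge": PopulationSample(**_MODERN),
            "Kostenki14": PopulationSample(1, 2.5),
            "Natufian": PopulationSample(6, 0.7),
            "CHG": PopulationSample(2, 5.0),
            "AAF": PopulationSample(5, (1.48, 0.8, 0.9, 0.76, 0.69)),
            "Levant_N": PopulationSample(2, (0.16, 0.75)),
            "ACF": PopulationSample(25, 1.0),
        }
        models = [
            QpAdmModelSpec(
                target="ACF",
                sources=("AAF", "Levant_N"),
                outgroups=("Mbuti", "Han", "Onge", "Kostenki14", "Natufian", "CHG"),
                true_weights=(lam, 1 - lam),
            )
        ]
        description = (
            "Ceramic farmers as a two-way mixture of the Aceramic farmer lineage "
            "(78.7%) and a Levantine Neolithic one (21.3%)."
        )
    elif name == "irongates_three_way":
        p_ahg, p_whg, p_ehg = 0.258, 0.629, 0.113
        lam_inner = p_whg / (p_whg + p_ehg)
        graph = AdmixtureGraph(
            root="Root",
            drift_edges=_backbone()
            + [
                DriftEdge("West2", "EurHG", 0.01),
                DriftEdge("West2", "NE", 0.04),
                DriftEdge("EurHG", "WHGb", 0.05),
                DriftEdge("WHGb", "GoyetQ2", 0.025),
                DriftEdge("WHGb", "WHGanc", 0.01),
                DriftEdge("WHGanc", "WHG", 0.01),
                DriftEdge("EurHG", "EHGb", 0.06),
                DriftEdge("EHGb", "MA1", 0.03),
                DriftEdge("EHGb", "EHGanc", 0.01),
                DriftEdge("EHGanc", "EHG", 0.012),
                DriftEdge("NE", "AnatB", 0.03),
                DriftEdge("AnatB", "AHGanc", 0.012),
                DriftEdge("AHGanc", "AHG", 0.015),
                DriftEdge("AnatB", "LevB", 0.008),
                DriftEdge("LevB", "Levant_N", 0.02),
                DriftEdge("IGmix", "IronGates", 0.005),
            ],
            admixture_events=[
                AdmixtureEvent("HGmix", "WHGanc", "EHGanc", lam_inner),
                AdmixtureEvent("IGmix", "AHGanc", "HGmix", p_ahg),
            ],
        )
        samples = {
            "Mbuti": PopulationSample(**_MODERN),
            "Han": PopulationSample(**_MODERN),
            "Onge": PopulationSample(**_MODERN),
            "Kostenki14": PopulationSample(1, 2.5),
            "GoyetQ2": PopulationSample(1, 1.0),
            "MA1": PopulationSample(1, 1.0),
            "Levant_N": PopulationSample(2, (0.16, 0.75)),
            "AHG": PopulationSample(1, 2.9),
            "WHG": PopulationSample(5, 2.0),
            "EHG": PopulationSample(3, 1.5),
            "IronGates": PopulationSample(10, 1.2),
        }
        models = [
            QpAdmModelSpec(
                target="IronGates",
                sources=("AHG", "WHG", "EHG"),
                outgroups=(
                    "Mbuti",
                    "Han",
                    "Onge",
                    "Kostenki14",
                    "GoyetQ2",
                    "MA1",
                    "Levant_N",
                ),
                true_weights=(p_ahg, p_whg, p_ehg),
            )
        ]
        description = (
            "Iron Gates hunter-gatherers as a three-way mixture of a Near-Eastern "
            "hunter-gatherer lineage (25.8%), WHG (62.9%) and EHG (11.3%)."
        )
    elif name == "basal_eurasian":
        a_ahg, a_nat = 0.248, 0.385
        graph = AdmixtureGraph(
            root="Root",
            drift_edges=[
                DriftEdge("Root", "Afr", 0.02),
                DriftEdge("Afr", "Mota", 0.05),
                DriftEdge("Root", "NonAfr", 0.04),
                DriftEdge("NonAfr", "Basal", 0.05),
                DriftEdge("NonAfr", "Crown", 0.03),
                DriftEdge("Crown", "UstIshim", 0.03),
                DriftEdge("Crown", "Crown2", 0.025),
                DriftEdge("Crown2", "East", 0.025),
                DriftEdge("East", "Han", 0.03),
                DriftEdge("East", "Onge", 0.04),
                DriftEdge("East", "Papuan", 0.05),
                DriftEdge("Crown2", "West", 0.035),
                DriftEdge("West", "Kostenki14", 0.03),
                DriftEdge("West", "MA1", 0.035),
                DriftEdge("West", "VillB", 0.03),
                DriftEdge("VillB", "Villabruna", 0.01),
                DriftEdge("AHGmix", "AHG", 0.015),
                DriftEdge("NatufMix", "Natufian", 0.01),
            ],
            admixture_events=[
                AdmixtureEvent("AHGmix", "Basal", "VillB", a_ahg),
                AdmixtureEvent("NatufMix", "Basal", "VillB", a_nat),
            ],
        )
        samples = {
            "Mota": PopulationSample(1, 8.0, pseudo_haploid=False),
            "Han": PopulationSample(**_MODERN),
            "Onge": PopulationSample(**_MODERN),
            "Papuan": PopulationSample(**_MODERN),
            "UstIshim": PopulationSample(1, 30.0, pseudo_haploid=False),
            "Kostenki14": PopulationSample(1, 2.5),
            "MA1": PopulationSample(1, 1.0),
            "Villabruna": PopulationSample(3, 2.0),
            "AHG": PopulationSample(1, 2.9),
            "Natufian": PopulationSample(6, 0.7),
        }
        outgroups = ("Han", "Onge", "Papuan", "UstIshim", "Kostenki14", "MA1")
        models = [
            QpAdmModelSpec(
                target="AHG",
                sources=("Mota", "Villabruna"),
                outgroups=outgroups,
                true_weights=(a_ahg, 1 - a_ahg),
            ),
            QpAdmModelSpec(
                target="Natufian",
                sources=("Mota", "Villabruna"),
                outgroups=outgroups,
                true_weights=(a_nat, 1 - a_nat),
            ),
        ]
        description = (
            "Basal Eurasian ancestry realized as an early-diverging lineage mixed "
            "into Near-Eastern leaves (alpha 0.248 for the AHG analog, 0.385 for "
            "the Natufian analog); a deep African leaf serves as the proxy and the "
            "outgroups are crown Eurasians without basal ancestry."
        )
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )

    config = SimulationConfig(n_snps=n_snps, samples=samples, seed=seed)
    return Scenario(name, graph, config, models, description)
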