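"""Configuration-driven orchestration of the full analysis ledger.

A run executes, in order and only where configured: synthetic-data simulation
(or EIGENSTRAT loading), coverage/mismatch QC, a D-statistic batch,
permutation tests, the qpAdm model ledger (with qpWave distinguishability
checks and optional nested comparisons), Basal-Eurasian alpha estimation, and
composed ancestry predictions.  Every output table carries provenance
metadata (seed, package version, config hash) and a run log records
per-stage SNP counts and warnings such as statistics below the reporting
threshold.

Determinism: a single mandatory seed fans out to per-stage seeds derived by
stable hashing of the stage name, so stages are reproducible independently of
which other stages are enabled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .admixmodel import (
    basal_alpha,
    build_f4_matrix,
    compose_alpha,
    nested_model_comparison,
    qpadm_fit,
    qpwave_rank_test,
)
from .eigendata import GenotypeDataset, read_eigenstrat
from .fstats import DEFAULT_MIN_SNPS, assign_blocks, dstat_batch
from .pcaproj import fit_pca, project_dataset
from .permtest import enumerate_scheme_a, permutation_test, sample_scheme_b
from .simgraph import SCENARIO_NAMES, study_scenario, simulate_dataset

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    pass


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisConfig:
    seed: int
    scenario: str | None = None
    n_snps: int = 50_000
    dataset_prefix: str | None = None
    pseudo_haploid: list[str] = field(default_factory=list)
    dstats: list[dict] = field(default_factory=list)
    permutations: list[dict] = field(default_factory=list)
    qpadm: list[dict] = field(default_factory=list)
    nested: list[dict] = field(default_factory=list)
    alpha: list[dict] = field(default_factory=list)
    compose: list[dict] = field(default_factory=list)
    pca: dict | None = None
    min_snps: int = DEFAULT_MIN_SNPS
    fit_p_threshold: float = 0.05
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ConfigError("config requires a seed")
        return cls(**data, raw=dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.raw or self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _referenced_populations(config: AnalysisConfig) -> set[str]:
    pops: set[str] = set()
    for d in config.dstats:
        pops |= {d["w"], d["x"], d["y"], d["z"]}
    for p in config.permutations:
        pops |= {p["test"], p["outgroup"]}
    for model in config.qpadm + config.nested:
        pops.add(model["target"])
        pops |= set(model.get("sources", []))
        pops |= set(model.get("full_sources", []))
        pops |= set(model.get("reduced_sources", []))
        pops |= set(model["outgroups"])
    for a in config.alpha:
        pops |= {a["target"], a["nonbasal_source"], a["basal_proxy"], *a["outgroups"]}
    if config.pca:
        pops |= set(config.pca.get("fit_populations", []))
        pops |= set(config.pca.get("project_populations", []))
    return pops


def validate_config(config: AnalysisConfig, dataset: GenotypeDataset) -> None:
    """Fail fast on dangling population references before any computation."""
    available = set(dataset.population_labels)
    missing = _referenced_populations(config) - available
    if missing:
        raise ConfigError(
            f"config references populations absent from the dataset: {sorted(missing)}"
        )


@dataclass
class ReportBundle:
    outdir: Path
    dataset: GenotypeDataset
    tables: dict[str, pd.DataFrame]
    provenance: dict[str, Any]
    log_lines: list[str]


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run(config: AnalysisConfig, outdir: str | Path) -> ReportBundle:
    """Execute all configured stages; see module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    provenance = dict(
        seed=config.seed,
        package_version=__version__,
        config_hash=config.config_hash(),
        scenario=config.scenario,
    )

    stage = "load"
    try:
        if config.scenario:
            if config.scenario not in SCENARIO_NAMES:
                raise ConfigError(
                    f"unknown scenario {config.scenario!r}; valid: {SCENARIO_NAMES}"
                )
            scen = study_scenario(
                config.scenario, n_snps=config.n_snps, seed=derive_seed(config.seed, "simulate")
            )
            dataset = simulate_dataset(scen.graph, scen.config)
            log.append(
                f"[simulate] scenario={scen.name} n_snps={dataset.n_snps} "
                f"n_individuals={dataset.n_individuals}"
            )
        elif config.dataset_prefix:
            p = config.dataset_prefix
            dataset = read_eigenstrat(
                f"{p}.geno", f"{p}.snp", f"{p}.ind", pseudo_haploid=config.pseudo_haploid
            )
            log.append(f"[load] prefix={p} n_snps={dataset.n_snps}")
        else:
            raise ConfigError("config needs either a scenario name or a dataset prefix")

        validate_config(config, dataset)
        blocks = assign_blocks(dataset)
        log.append(f"[blocks] n_blocks={blocks.n_blocks} unit={blocks.unit}")

        if config.dstats:
            stage = "dstat"
            quads = [(d["w"], d["x"], d["y"], d["z"]) for d in config.dstats]
            df = dstat_batch(dataset, quads, blocks, min_snps=config.min_snps)
            n_low = int(df["below_threshold"].sum())
            if n_low:
                log.append(
                    f"[dstat] WARNING: {n_low} statistics below the "
                    f"{config.min_snps}-SNP reporting threshold"
                )
            log.append(f"[dstat] computed {len(df)} statistics")
            tables["dstats"] = df

        if config.permutations:
            stage = "permtest"
            rows = []
            rng_seed = derive_seed(config.seed, "permtest")
            for i, spec in enumerate(config.permutations):
                g1 = list(spec["group1"])
                g2 = list(spec["group2"])
                scheme = spec.get("scheme", "random-split")
                if scheme == "exhaustive-leave-one":
                    assignments = enumerate_scheme_a(
                        g1, g2[0], include_anchor=spec.get("include_anchor", True),
                        expected_group_size=None,
                    )
                else:
                    assignments = sample_scheme_b(
                        g1, g2, n_perm=spec.get("n_perm", 1000),
                        rng=rng_seed + i, expected_sizes=None,
                    )
                res = permutation_test(
                    dataset, g1, g2, assignments, spec["test"], spec["outgroup"], blocks
                )
                rows.append(
                    dict(
                        test_population=spec["test"],
                        scheme=scheme,
                        observed_D=res.observed_d,
                        n_perm=len(assignments),
                        n_ge=res.n_ge,
                        n_total=res.n_total,
                        empirical_P=res.empirical_p,
                        identity_inclusive=res.identity_inclusive,
                    )
                )
            tables["permutations"] = pd.DataFrame(rows)
            log.append(f"[permtest] ran {len(rows)} permutation tests")

        if config.qpadm:
            stage = "qpadm"
            rows = []
            for spec in config.qpadm:
                sources = tuple(spec["sources"])
                outgroups = tuple(spec["outgroups"])
                src_f4m = build_f4_matrix(dataset, sources, outgroups, blocks) if len(sources) > 1 else None
                wave_p = (
                    qpwave_rank_test(src_f4m, len(sources) - 2).p_value
                    if len(sources) > 2
                    else (qpwave_rank_test(src_f4m, 0).p_value if len(sources) == 2 else float("nan"))
                )
                fit = qpadm_fit(dataset, spec["target"], sources, outgroups, blocks)
                row = dict(
                    target=fit.target,
                    sources=",".join(sources),
                    outgroups=",".join(outgroups),
                    chi2=fit.chi2,
                    dof=fit.dof,
                    p_value=fit.p_value,
                    feasible=fit.feasible,
                    n_snps=fit.n_snps,
                    sources_distinguishable_p=wave_p,
                )
                for s, wt, se in zip(sources, fit.weights, fit.weight_se):
                    row[f"weight_{s}"] = wt
                    row[f"se_{s}"] = se
                rows.append(row)
            tables["qpadm"] = pd.DataFrame(rows)
            log.append(f"[qpadm] fitted {len(rows)} models")

        if config.nested:
            stage = "nested"
            rows = []
            for spec in config.nested:
                cmp_res = nested_model_comparison(
                    dataset,
                    spec["target"],
                    spec["full_sources"],
                    spec["reduced_sources"],
                    spec["outgroups"],
                    blocks,
                    threshold=config.fit_p_threshold,
                )
                rows.append(
                    dict(
                        target=spec["target"],
                        full_sources=",".join(spec["full_sources"]),
                        reduced_sources=",".join(spec["reduced_sources"]),
                        full_p=cmp_res.full.p_value,
                        reduced_p=cmp_res.reduced.p_value,
                        reduced_rejected=cmp_res.reduced_rejected,
                        preferred=cmp_res.preferred,
                    )
                )
            tables["nested"] = pd.DataFrame(rows)
            log.append(f"[nested] compared {len(rows)} model pairs")

        if config.alpha:
            stage = "alpha"
            rows = []
            for spec in config.alpha:
                est = basal_alpha(
                    dataset,
                    spec["target"],
                    spec["nonbasal_source"],
                    spec["basal_proxy"],
                    spec["outgroups"],
                    blocks,
                )
                rows.append(
                    dict(
                        population=est.population,
                        alpha=est.alpha,
                        se=est.se,
                        basal_proxy=est.basal_proxy,
                        nonbasal_source=est.nonbasal_source,
                        fit_p=est.fit.p_value,
                        within_unit_interval=est.within_unit_interval,
                    )
                )
            tables["alpha"] = pd.DataFrame(rows)
            log.append(f"[alpha] estimated {len(rows)} basal proportions")

        if config.compose:
            stage = "compose"
            tables["composed"] = compose_report(
                tables.get("qpadm"), tables.get("alpha"), config.compose
            )
            log.append(f"[compose] produced {len(tables['composed'])} predictions")

        if config.pca:
            stage = "pca"
            spec = config.pca
            fit_ids = [
                iid
                for iid, pop in zip(dataset.individual_ids, dataset.population_labels)
                if pop in set(spec.get("fit_populations", []))
            ]
            model = fit_pca(
                dataset, fit_ids, spec.get("n_components", 2),
                min_completeness=spec.get("min_completeness", 0.9),
            )
            proj_ids = [
                iid
                for iid, pop in zip(dataset.individual_ids, dataset.population_labels)
                if pop in set(spec.get("project_populations", []))
            ]
            tables["pca"] = project_dataset(dataset, model, fit_ids + proj_ids)
            log.append(
                f"[pca] fitted {model.n_components} components on {len(fit_ids)} "
                f"individuals, projected {len(proj_ids)}"
            )
    except ConfigError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        for name, df in tables.items():
            _write_table(df, outdir / f"{name}.tsv")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, df in tables.items():
        _write_table(df, outdir / f"{name}.tsv")
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return ReportBundle(outdir, dataset, tables, provenance, log)


def compose_report(
    qpadm_table: pd.DataFrame | None,
    alpha_table: pd.DataFrame | None,
    requests: Sequence[dict],
) -> pd.DataFrame:
    """Composed alpha predictions with side-by-side direct estimates.

    Each request either names a fitted model leg (``target`` + ``source``,
    resolved in the qpAdm table, and ``alpha_of`` resolved in the alpha
    table) or carries explicit numeric inputs (``proportion``,
    ``proportion_se``, ``alpha``, ``alpha_se``).
    """
    rows = []
    for req in requests:
        if "proportion" in req:
            p, sp = float(req["proportion"]), float(req.get("proportion_se", 0.0))
            a, sa = float(req["alpha"]), float(req.get("alpha_se", 0.0))
            label = req.get("label", "explicit")
            direct = direct_se = float("nan")
        else:
            label = req.get("label", f"{req['target']}<-{req['source']}")
            if qpadm_table is None or alpha_table is None:
                raise ConfigError("compose request references fits that were not run")
            hit = qpadm_table[qpadm_table["target"] == req["target"]]
            if hit.empty or f"weight_{req['source']}" not in hit.columns:
                raise ConfigError(
                    f"no qpAdm fit for target {req['target']!r} with source {req['source']!r}"
                )
            p = float(hit.iloc[0][f"weight_{req['source']}"])
            sp = float(hit.iloc[0][f"se_{req['source']}"])
            src_alpha = alpha_table[alpha_table["population"] == req["alpha_of"]]
            if src_alpha.empty:
                raise ConfigError(f"no alpha estimate for {req['alpha_of']!r}")
            a = float(src_alpha.iloc[0]["alpha"])
            sa = float(src_alpha.iloc[0]["se"])
            direct_hit = alpha_table[alpha_table["population"] == req["target"]]
            direct = float(direct_hit.iloc[0]["alpha"]) if not direct_hit.empty else float("nan")
            direct_se = float(direct_hit.iloc[0]["se"]) if not direct_hit.empty else float("nan")
        comp = compose_alpha(p, sp, a, sa)
        rows.append(
            dict(
                label=label,
                proportion=p,
                proportion_se=sp,
                alpha_source=a,
                alpha_source_se=sa,
                composed_alpha=comp.estimate,
                composed_se=comp.se,
                direct_alpha=direct,
                direct_alpha_se=direct_se,
            )
        )
    return pd.DataFrame(rows)
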