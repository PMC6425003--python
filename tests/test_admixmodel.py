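"""f4 matrices, rank tests, qpAdm fits, basal alpha and composed predictions."""

import numpy as np
import pytest
from scipy import stats as sps

from fstatkit.admixmodel import (
    F4Matrix,
    basal_alpha,
    build_f4_matrix,
    compose_alpha,
    nested_model_comparison,
    qpadm_fit,
    qpwave_rank_test,
)
from fstatkit.fstats import assign_blocks, f4_statistic, jackknife_covariance
from fstatkit.simgraph import (
    AdmixtureEvent,
    AdmixtureGraph,
    DriftEdge,
    PopulationSample,
    SimulationConfig,
    simulate_dataset,
)

from conftest import random_dataset


def two_source_graph(lam=None, target_parent=None):
    """Small well-identified graph: sources S1/S2 with on-path outgroups.

    ``lam`` mixes the target from S1anc/S2anc; ``target_parent`` instead
    clones the target from one internal node (lam takes precedence).
    """
    edges = [
        DriftEdge("Root", "Mb", 0.10),
        DriftEdge("Root", "NA", 0.05),
        DriftEdge("NA", "O1", 0.03),
        DriftEdge("NA", "W", 0.02),
        DriftEdge("W", "O2", 0.03),
        DriftEdge("W", "W2", 0.01),
        DriftEdge("W2", "S1b", 0.05),
        DriftEdge("W2", "S2b", 0.05),
        DriftEdge("S1b", "O3", 0.02),
        DriftEdge("S1b", "S1anc", 0.01),
        DriftEdge("S1anc", "S1", 0.01),
        DriftEdge("S2b", "O4", 0.02),
        DriftEdge("S2b", "S2anc", 0.01),
        DriftEdge("S2anc", "S2", 0.01),
    ]
    admix = []
    if lam is not None:
        admix = [AdmixtureEvent("Tmix", "S1anc", "S2anc", lam)]
        edges.append(DriftEdge("Tmix", "T", 0.005))
    elif target_parent is not None:
        edges.append(DriftEdge(target_parent, "T", 0.0))
    return AdmixtureGraph("Root", edges, admix)


OUTGROUPS = ("Mb", "O1", "O2", "O3", "O4")


def simulate(graph, seed, n_snps=20_000, extra=()):
    samples = {p: PopulationSample(5, 30.0, pseudo_haploid=False)
               for p in ["Mb", "O1", "O2", "O3", "O4", "S1", "S2", "T", *extra]
               if p in graph.nodes}
    cfg = SimulationConfig(n_snps=n_snps, samples=samples, seed=seed)
    return simulate_dataset(graph, cfg)


class TestF4Matrix:
    def test_two_by_two_matches_f4_statistic(self, rng):
        ds = random_dataset(
            rng, n_snps=400, pops=("A", "B", "C", "D"), n_per_pop=3, missing_rate=0.0
        )
        blocks = assign_blocks(ds)
        f4m = build_f4_matrix(ds, ("A", "B"), ("C", "D"), blocks)
        st = f4_statistic(ds, "A", "B", "C", "D", blocks, min_snps=0)
        assert f4m.values[0, 0] == pytest.approx(st.estimate, abs=1e-14)
        assert np.sqrt(f4m.covariance[0, 0]) == pytest.approx(st.se, rel=1e-10)

    def test_duplicated_left_population_gives_zero_row(self, rng):
        ds = random_dataset(rng, n_snps=300, pops=("A", "C", "D", "E"), n_per_pop=3)
        from fstatkit.eigendata import GenotypeDataset, IndividualRecord

        dup = GenotypeDataset(
            ds.snps,
            ds.individuals + [IndividualRecord(f"Ac{k}", "U", "Acopy") for k in range(3)],
            np.hstack([ds.genotypes, ds.genotypes[:, :3]]),
            np.concatenate([ds.pseudo_haploid, ds.pseudo_haploid[:3]]),
        )
        f4m = build_f4_matrix(dup, ("A", "Acopy"), ("C", "D", "E"), assign_blocks(dup))
        assert np.allclose(f4m.values, 0.0, atol=1e-15)

    def test_overlapping_left_right_rejected(self, small_dataset):
        blocks = assign_blocks(small_dataset)
        with pytest.raises(ValueError, match="both left and right"):
            build_f4_matrix(small_dataset, ("A", "B"), ("B", "C"), blocks)

    def test_covariance_psd_and_diag_close_to_f4_variances(self):
        graph = two_source_graph(lam=0.5)
        ds = simulate(graph, seed=21)
        blocks = assign_blocks(ds)
        f4m = build_f4_matrix(ds, ("T", "S1", "S2"), OUTGROUPS, blocks)
        eig = np.linalg.eigvalsh(f4m.covariance)
        assert eig.min() >= -1e-18
        # diagonal vs per-statistic jackknife on the same SNP set: the matrix
        # shares one intersection set, so restrict the dataset to it first
        table_pops = ["T", "S1", "S2", *OUTGROUPS]
        from fstatkit.eigendata import allele_frequencies

        counts = allele_frequencies(ds, table_pops).allele_counts
        keep = np.flatnonzero((counts > 0).all(axis=1))
        sub = ds.subset(snp_indices=keep)
        sub_blocks = assign_blocks(sub)
        st = f4_statistic(sub, "T", "S1", "Mb", "O1", sub_blocks, min_snps=0)
        assert np.sqrt(f4m.covariance[0, 0]) == pytest.approx(st.se, rel=0.10)


class TestRankTest:
    def test_exact_low_rank_matrix_fits_perfectly(self, rng):
        a = rng.normal(size=(3, 1))
        b = rng.normal(size=(1, 5))
        x = a @ b
        d = x.size
        cov = np.eye(d) * 1e-6
        f4m = F4Matrix(
            left=("L0", "L1", "L2", "L3"),
            right=tuple(f"R{i}" for i in range(6)),
            values=x,
            covariance=cov,
            block_sums=np.stack([x, x]) * 0.5,
            block_counts=np.array([1.0, 1.0]),
            n_snps=2,
        )
        res = qpwave_rank_test(f4m, 1)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.999
        assert res.dof == (3 - 1) * (5 - 1)

    def test_one_by_one_equals_squared_z(self, rng):
        x = np.array([[0.003]])
        q = np.array([[1.2e-6]])
        f4m = F4Matrix(
            left=("L0", "L1"),
            right=("R0", "R1"),
            values=x,
            covariance=q,
            block_sums=np.stack([x, x]) * 0.5,
            block_counts=np.array([1.0, 1.0]),
            n_snps=2,
        )
        res = qpwave_rank_test(f4m, 0)
        assert res.chi2 == pytest.approx(x[0, 0] ** 2 / q[0, 0], rel=1e-12)
        assert res.dof == 1

    def test_invalid_rank_rejected(self, rng):
        x = rng.normal(size=(2, 3))
        f4m = F4Matrix(
            left=("a", "b", "c"),
            right=("d", "e", "f", "g"),
            values=x,
            covariance=np.eye(6),
            block_sums=np.stack([x, x]),
            block_counts=np.array([1.0, 1.0]),
            n_snps=2,
        )
        with pytest.raises(ValueError, match="testable ranks"):
            qpwave_rank_test(f4m, 2)

    def test_chi2_invariant_to_right_reordering(self):
        graph = two_source_graph(lam=0.7)
        ds = simulate(graph, seed=8)
        blocks = assign_blocks(ds)
        a = build_f4_matrix(ds, ("S1", "S2", "T"), OUTGROUPS, blocks)
        reordered = (OUTGROUPS[0],) + tuple(reversed(OUTGROUPS[1:]))
        b = build_f4_matrix(ds, ("S1", "S2", "T"), reordered, blocks)
        ra = qpwave_rank_test(a, 1)
        rb = qpwave_rank_test(b, 1)
        assert ra.chi2 == pytest.approx(rb.chi2, rel=1e-6)

    def test_distinguishable_sources_reject_rank_zero(self):
        graph = two_source_graph(lam=0.5)
        ds = simulate(graph, seed=13)
        blocks = assign_blocks(ds)
        f4m = build_f4_matrix(ds, ("S1", "S2"), OUTGROUPS, blocks)
        assert qpwave_rank_test(f4m, 0).p_value < 1e-6


class TestQpAdm:
    def test_target_copy_of_source_gets_full_weight(self):
        graph = two_source_graph(target_parent="S1anc")
        ds = simulate(graph, seed=31)
        blocks = assign_blocks(ds)
        fit = qpadm_fit(ds, "T", ("S1", "S2"), OUTGROUPS, blocks)
        assert fit.weights[0] == pytest.approx(1.0, abs=0.05)
        assert fit.weights[1] == pytest.approx(0.0, abs=0.05)
        # a boundary truth may land a hair outside [0,1]; the fit must be adequate
        assert fit.p_value > 0.001

    def test_weights_sum_to_one_and_permute_with_sources(self):
        graph = two_source_graph(lam=0.7)
        ds = simulate(graph, seed=5)
        blocks = assign_blocks(ds)
        fit = qpadm_fit(ds, "T", ("S1", "S2"), OUTGROUPS, blocks)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-10)
        swapped = qpadm_fit(ds, "T", ("S2", "S1"), OUTGROUPS, blocks)
        assert swapped.weights[::-1] == pytest.approx(fit.weights, abs=1e-6)

    def test_two_way_mixture_recovered_within_three_se(self):
        lam = 0.7
        graph = two_source_graph(lam=lam)
        ds = simulate(graph, seed=77)
        blocks = assign_blocks(ds)
        fit = qpadm_fit(ds, "T", ("S1", "S2"), OUTGROUPS, blocks)
        assert abs(fit.weights[0] - lam) < 3 * fit.weight_se[0]
        assert fit.p_value > 0.001

    def test_two_way_grid_bias_and_coverage(self):
        """Across true proportions 0.1..0.9: small bias, ~95% within 2 SE."""
        lams = (0.1, 0.25, 0.5, 0.75, 0.9)
        reps = 10
        errors, covered = [], 0
        for i, lam in enumerate(lams):
            for rep in range(reps):
                graph = two_source_graph(lam=lam)
                ds = simulate(graph, seed=7000 + 100 * i + rep, n_snps=100_000)
                blocks = assign_blocks(ds)
                fit = qpadm_fit(ds, "T", ("S1", "S2"), OUTGROUPS, blocks)
                errors.append(fit.weights[0] - lam)
                covered += abs(fit.weights[0] - lam) < 2 * fit.weight_se[0]
        assert np.mean(np.abs(errors)) < 0.03
        # nominal 95% coverage; 3 binomial sigma below with n = 50 draws
        assert covered / len(errors) >= 0.85

    def test_misspecified_target_rejected_or_infeasible(self):
        """A target on its own independent branch is not a source mixture."""
        bad = 0
        for seed in range(6):
            graph = two_source_graph(target_parent="W2")
            ds = simulate(graph, seed=200 + seed)
            blocks = assign_blocks(ds)
            fit = qpadm_fit(ds, "T", ("S1", "S2"), OUTGROUPS, blocks)
            if fit.p_value < 0.05 or not fit.feasible:
                bad += 1
        assert bad >= 4

    def test_insufficient_outgroups_rejected(self, small_dataset):
        blocks = assign_blocks(small_dataset)
        with pytest.raises(ValueError, match="outgroups"):
            qpadm_fit(small_dataset, "A", ("B", "C"), ("D",), blocks)

    def test_single_source_degenerates_to_cladality_test(self):
        graph = two_source_graph(target_parent="S1anc")
        ds = simulate(graph, seed=41)
        blocks = assign_blocks(ds)
        fit = qpadm_fit(ds, "T", ("S1",), OUTGROUPS, blocks)
        assert fit.weights == pytest.approx([1.0])
        f4m = build_f4_matrix(ds, ("T", "S1"), OUTGROUPS, blocks)
        rank0 = qpwave_rank_test(f4m, 0)
        assert fit.chi2 == pytest.approx(rank0.chi2, rel=1e-10)
        assert fit.dof == rank0.dof == len(OUTGROUPS) - 1


class TestNestedComparison:
    def test_non_subset_rejected(self, small_dataset):
        blocks = assign_blocks(small_dataset)
        with pytest.raises(ValueError, match="subset"):
            nested_model_comparison(
                small_dataset, "A", ["B"], ["B", "C"], ["D"], blocks
            )

    def test_reduced_true_model_preferred(self):
        graph = two_source_graph(target_parent="S1anc")
        ds = simulate(graph, seed=55)
        blocks = assign_blocks(ds)
        res = nested_model_comparison(
            ds, "T", ["S1", "S2"], ["S1"], OUTGROUPS, blocks
        )
        assert res.preferred == "reduced"
        assert res.reduced.p_value > 0.05

    def test_missing_second_source_degrades_fit(self):
        """True two-way target: dropping the 30% source hurts the fit."""
        hits = 0
        for seed in range(6):
            graph = two_source_graph(lam=0.7)
            ds = simulate(graph, seed=300 + seed, n_snps=30_000)
            blocks = assign_blocks(ds)
            res = nested_model_comparison(
                ds, "T", ["S1", "S2"], ["S1"], OUTGROUPS, blocks
            )
            if res.reduced.p_value < 0.05 and res.full.p_value >= 0.05:
                hits += 1
        assert hits >= 4


class TestBasalAlpha:
    def test_copy_targets_give_extreme_alphas(self):
        graph = two_source_graph(target_parent="S1anc")
        ds = simulate(graph, seed=61)
        blocks = assign_blocks(ds)
        est = basal_alpha(ds, "T", nonbasal_source="S2", basal_proxy="S1",
                          outgroups=OUTGROUPS, blocks=blocks)
        assert est.alpha == pytest.approx(1.0, abs=0.05)
        est2 = basal_alpha(ds, "T", nonbasal_source="S1", basal_proxy="S2",
                           outgroups=OUTGROUPS, blocks=blocks)
        assert est2.alpha == pytest.approx(0.0, abs=0.05)


class TestComposeAlpha:
    def test_reproduces_published_pair_at_one_decimal(self):
        comp = compose_alpha(0.258, 0.050, 0.248, 0.055)
        assert comp.as_percent() == (6.4, 1.9)

    def test_identity_factor(self):
        comp = compose_alpha(1.0, 0.0, 0.33, 0.07)
        assert comp.estimate == pytest.approx(0.33)
        assert comp.se == pytest.approx(0.07)

    def test_zero_proportion_gives_zero(self):
        comp = compose_alpha(0.0, 0.0, 0.4, 0.1)
        assert comp.estimate == 0.0
        assert comp.se == 0.0

    def test_delta_method_matches_monte_carlo(self):
        rng = np.random.default_rng(123)
        p, sp, a, sa = 0.258, 0.050, 0.248, 0.055
        draws = rng.normal(p, sp, 1_000_000) * rng.normal(a, sa, 1_000_000)
        comp = compose_alpha(p, sp, a, sa)
        assert comp.se == pytest.approx(draws.std(), rel=0.05)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            compose_alpha(0.5, -0.1, 0.5, 0.1)
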