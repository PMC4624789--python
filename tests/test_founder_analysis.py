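"""Founder identification, migration-time scans, epoch partitioning."""

import numpy as np
import pytest

from mitofounder import (
    CLOCKS,
    SimConfig,
    build_mj_network,
    compare_sink_allocations,
    default_grid,
    founders_from_truth,
    identify_founders,
    parse_variant_string,
    partition_epochs,
    reciprocal_fa,
    scan_migration_times,
    simulate_source_sink,
)
from mitofounder.founder_analysis import FounderCluster
from mitofounder.mj_network import NetworkNode
from mitofounder.rho_dating import tree_from_paths


def hp(text, sample_id, population, role):
    return parse_variant_string(
        text, sample_id=sample_id, population=population, region_role=role
    )


@pytest.fixture
def toy_network():
    """Founder candidate {16172C} shared by source+sink, with two
    source-private derived branches and a sink-private branch."""
    hs = [
        hp("16172C", "src1", "SRC", "source"),
        hp("16172C 16219G", "src2", "SRC", "source"),
        hp("16172C 16278T", "src3", "SRC", "source"),
        hp("16172C", "snk1", "SNK", "sink"),
        hp("16172C 16126C", "snk2", "SNK", "sink"),
    ]
    return build_mj_network(hs)


class TestIdentifyFounders:
    def test_shared_node_with_two_derived_branches_passes_f1_f2(self, toy_network):
        for crit in ("f0", "f1", "f2"):
            clusters = identify_founders(toy_network, "SRC", "SNK", crit)
            assert len(clusters) == 1
            c = clusters[0]
            assert c.founder_node.sites == frozenset({16172})
            assert c.source_derived_branches == 2
            assert c.passes_f1 and c.passes_f2
            assert set(c.sink_samples) == {"snk1", "snk2"}

    def test_tipless_founder_passes_f0_only(self):
        hs = [
            hp("16172C", "src1", "SRC", "source"),
            hp("16172C", "snk1", "SNK", "sink"),
            hp("16172C 16126C", "snk2", "SNK", "sink"),
        ]
        net = build_mj_network(hs)
        assert len(identify_founders(net, "SRC", "SNK", "f0")) == 1
        assert identify_founders(net, "SRC", "SNK", "f1") == []
        assert identify_founders(net, "SRC", "SNK", "f2") == []

    def test_sink_clade_one_step_from_source_forms_one_cluster(self):
        hs = [
            hp("", "src1", "SRC", "source"),
            hp("16219G", "src2", "SRC", "source"),
            hp("16172C", "snk1", "SNK", "sink"),
            hp("16172C 16126C", "snk2", "SNK", "sink"),
            hp("16172C 16294T", "snk3", "SNK", "sink"),
        ]
        net = build_mj_network(hs)
        clusters = identify_founders(net, "SRC", "SNK", "f0")
        assert len(clusters) == 1
        c = clusters[0]
        assert set(c.sink_samples) == {"snk1", "snk2", "snk3"}
        assert max(len(b.branches()) for b in [c.private_tree]) >= 1
        assert c.private_tree.n_leaves() == 3
        # snk1 is one step from the founder; its path carries 1 mutation
        assert c.rho() == pytest.approx((1 + 2 + 2) / 3)

    def test_criterion_nesting_on_random_synthetic_data(self):
        for seed in range(12):
            cfg = SimConfig(
                seed=seed,
                n_source_lineages=15,
                n_sink_samples=20,
                migration_events=((6_000.0, 3),),
            )
            net = build_mj_network(simulate_source_sink(cfg).haplotypes)
            ids = {
                crit: {
                    c.founder_node.node_id
                    for c in identify_founders(net, "Source", "Sink", crit)
                }
                for crit in ("f0", "f1", "f2")
            }
            assert ids["f2"] <= ids["f1"] <= ids["f0"]

    def test_source_equals_sink_rejected(self, toy_network):
        with pytest.raises(ValueError):
            identify_founders(toy_network, "SRC", "SRC")


def cluster(fid, n, M_per_leaf):
    """A star founder cluster with n leaves carrying given private counts."""
    paths = {f"s{i}": [m] for i, m in enumerate(M_per_leaf)}
    node = NetworkNode(node_id=fid, sites=frozenset({hash(fid) % 300 + 16051}),
                       samples=(("x", "SRC", "source"),))
    return FounderCluster(
        founder_node=node,
        sink_samples=tuple(sorted(paths)),
        private_tree=tree_from_paths(paths, root_label=fid),
        source_derived_branches=1,
    )


class TestMigrationScan:
    def test_zero_private_mutations_mode_at_zero(self):
        # Poisson(0; 0) = 1 by the limit convention; with no private
        # mutations the posterior decays geometrically from t=0
        scan = scan_migration_times([cluster("f", 3, [0, 0, 0])], "hvs1")
        assert scan.mode() == 0.0
        assert np.all(np.diff(scan.aggregate) < 0)

    def test_single_mutation_mode_near_clock_rate(self):
        # n=1, M=1: Poisson(1; t/r) maximised at t = r = 16,677 y
        scan = scan_migration_times([cluster("f", 1, [1])], "hvs1",
                                    grid=default_grid(60_000, 200))
        assert abs(scan.mode() - 16_677) <= 200

    def test_mass_sums_to_one_and_order_invariant(self):
        rng = np.random.default_rng(5)
        clusters = [
            cluster(f"f{i}", 4, list(rng.poisson(1.5, size=4))) for i in range(8)
        ]
        scan = scan_migration_times(clusters, "hvs1")
        assert scan.aggregate.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(scan.per_founder.sum(axis=1), 1.0, atol=1e-12)
        rev = scan_migration_times(clusters[::-1], "hvs1")
        assert np.allclose(scan.aggregate, rev.aggregate)

    def test_empty_founder_list_rejected(self):
        with pytest.raises(ValueError):
            scan_migration_times([], "hvs1")

    def test_simulated_migration_time_recovered(self):
        hits = 0
        for seed in range(20):
            res = simulate_source_sink(
                SimConfig(seed=seed, n_source_lineages=20, n_sink_samples=12_000,
                          migration_events=((8_000.0, 50),))
            )
            scan = scan_migration_times(founders_from_truth(res), "hvs1")
            hits += abs(scan.mode() - 8_000.0) <= 200
        assert hits >= 18

    def test_complete_clock_sharper_than_hvs1(self):
        """Matched simulations: the complete-mtDNA clock yields a
        lower-entropy aggregate posterior than the HVS-I clock."""
        entropies = {}
        for clock in ("fa_complete", "hvs1"):
            r = CLOCKS[clock].years_per_mutation
            res = simulate_source_sink(
                SimConfig(seed=11, n_source_lineages=20, n_sink_samples=500,
                          years_per_mutation=r,
                          migration_events=((8_000.0, 25),))
            )
            entropies[clock] = scan_migration_times(
                founders_from_truth(res), clock
            ).entropy()
        assert entropies["fa_complete"] < entropies["hvs1"]


class TestPartitionEpochs:
    def test_zero_mutations_favour_youngest_epoch(self):
        # monotone likelihood: e^(-n t / r) always prefers the smaller epoch
        few = partition_epochs([cluster("f", 4, [0, 0, 0, 0])], "hvs1")
        assert few.fractions[0] > few.fractions[1]
        many = partition_epochs([cluster("f", 10, [0] * 10)], "hvs1")
        assert many.fractions[0] > 0.9

    def test_founder_at_eight_ky_gets_mass_on_late_epoch(self):
        # private rho*r ~ 8,000 y: n=10 leaves, M = 10*8000/16677 ~ 5
        model = partition_epochs([cluster("f", 10, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])],
                                 "hvs1")
        assert model.fractions[1] >= 0.95

    def test_two_epoch_recovery(self):
        devs = []
        for seed in range(20):
            res = simulate_source_sink(
                SimConfig(seed=seed, n_source_lineages=20, n_sink_samples=200,
                          migration_events=((500.0, 25), (8_000.0, 25)))
            )
            model = partition_epochs(founders_from_truth(res), "hvs1")
            devs.append(abs(model.fractions[0] - 0.5))
        assert max(devs) <= 0.10

    def test_duplicate_epochs_rejected(self):
        with pytest.raises(ValueError):
            partition_epochs([cluster("f", 2, [0, 0])], "hvs1", epochs=(500, 500))


class TestCompareSinkAllocations:
    def test_identical_runs_full_overlap(self):
        clusters = [cluster(f"f{i}", 3, [1, 0, 0]) for i in range(5)]
        m = partition_epochs(clusters, "hvs1")
        report = compare_sink_allocations(m, m)
        assert report.overlap == 1.0
        assert report.shared_founders == 5

    def test_disjoint_modal_epochs_zero_overlap(self):
        young = [cluster("f1", 4, [0, 0, 0, 0])]
        old = [
            FounderCluster(
                founder_node=young[0].founder_node,
                sink_samples=("a", "b", "c", "d"),
                private_tree=tree_from_paths({s: [2] for s in "abcd"}),
                source_derived_branches=1,
            )
        ]
        ma = partition_epochs(young, "hvs1")
        mb = partition_epochs(old, "hvs1")
        assert compare_sink_allocations(ma, mb).overlap == 0.0

    def test_constructed_case_equals_hand_tally(self):
        # 10 founders: 6 young (modal epoch 500) with n=2, 4 old (modal
        # 8000) with n=5; second run flips the last young founder to old
        def runs():
            a, b = [], []
            for i in range(6):
                a.append(cluster(f"y{i}", 2, [0, 0]))
                b.append(cluster(f"y{i}", 2, [0, 0] if i < 5 else [2, 2]))
            for i in range(4):
                a.append(cluster(f"o{i}", 5, [1, 1, 1, 1, 1]))
                b.append(cluster(f"o{i}", 5, [1, 1, 1, 1, 1]))
            return a, b

        a, b = runs()
        report = compare_sink_allocations(
            partition_epochs(a, "hvs1"), partition_epochs(b, "hvs1")
        )
        # weights: total n = 6*2 + 4*5 = 32; discordant founder y5 has n=2
        assert report.overlap == pytest.approx(30 / 32)

    def test_disjoint_founder_sets_empty_report(self):
        ma = partition_epochs([cluster("a", 2, [0, 0])], "hvs1")
        mb = partition_epochs([cluster("b", 2, [0, 0])], "hvs1")
        report = compare_sink_allocations(ma, mb)
        assert report.empty and report.shared_founders == 0


class TestReciprocalFA:
    def _simulate_net(self, seed):
        cfg = SimConfig(seed=seed, n_source_lineages=40, n_sink_samples=60,
                        source_descendants_per_founder=4,
                        migration_events=((8_000.0, 6),))
        return build_mj_network(simulate_source_sink(cfg).haplotypes)

    def test_unidirectional_migration_flags_true_source(self):
        net = self._simulate_net(2)
        rec = reciprocal_fa(net, "Source", "Sink", clock="hvs1", criterion="f0")
        assert rec.supported_source == "Source"
        assert rec.private_diversity_sink_a > rec.private_diversity_sink_b

    def test_reverse_direction_mode_biased_old(self):
        fwd, rev = [], []
        for seed in (1, 2, 3, 4, 5):
            rec = reciprocal_fa(self._simulate_net(seed), "Source", "Sink",
                                clock="hvs1", criterion="f0")
            fwd.append(rec.scan_a_as_source.mode())
            rev.append(rec.scan_b_as_source.mode())
        assert np.mean(rev) > np.mean(fwd)

    def test_symmetric_sharing_is_ambiguous(self):
        # single shared haplotype, no private diversity either side
        hs = [
            hp("16172C", "a1", "A", "unassigned"),
            hp("16172C", "b1", "B", "unassigned"),
        ]
        net = build_mj_network(hs)
        rec = reciprocal_fa(net, "A", "B", clock="hvs1", criterion="f0")
        assert rec.supported_source == "ambiguous"
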