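"""DMP calling, direction/region/window summaries, and the chrX mode."""

import numpy as np
import pytest

from deltameth.datatypes import (
    Direction,
    DmpCall,
    GenomeLayout,
    RegionGroup,
    annotations_by_probe,
)
from deltameth.dmp import (
    call_dmps,
    compute_delta,
    direction_split,
    global_summary,
    percent_of_probes,
    region_distribution,
    window_counts,
    x_hypomethylation_analysis,
)
from deltameth.simulate import PlantedEffect, SimulationConfig, generate_manifest, generate_pools

from conftest import ann, pools


def make_call(probe_id, delta, entries=(), chrom="1", pos=1):
    return DmpCall(
        probe_id=probe_id,
        delta_me=delta,
        direction=Direction.HYPER if delta > 0 else Direction.HYPO,
        chrom=chrom,
        pos=pos,
        gene_entries=tuple((g, RegionGroup.parse(r)) for g, r in entries),
    )


class TestDeltaAndCalling:
    def test_delta_is_female_minus_male(self):
        data = pools(["a", "b", "c"], [0.5, 0.3, 1.0], [0.7, 0.3, 0.0])
        assert list(compute_delta(data)) == pytest.approx([0.2, 0.0, -1.0])

    def test_threshold_boundary_is_strict(self):
        # deltas: exactly +0.2 (not called), +0.21 (hyper), -0.21 (hypo)
        manifest = [ann("a"), ann("b"), ann("c")]
        data = pools(["a", "b", "c"], [0.0, 0.0, 0.21], [0.2, 0.21, 0.0])
        calls = call_dmps(data, manifest, threshold=0.20)
        assert [(c.probe_id, c.direction) for c in calls] == [
            ("b", Direction.HYPER), ("c", Direction.HYPO)
        ]

    def test_calls_sorted_by_genome_position(self, tiny_manifest, tiny_pools):
        calls = call_dmps(tiny_pools, tiny_manifest, threshold=0.20)
        keys = [(c.chrom, c.pos) for c in calls]
        assert keys == [("1", 50), ("2", 10), ("X", 123), ("Y", 456)]

    def test_noise_free_planted_calls_equal_truth(self):
        config = SimulationConfig(
            n_probes_per_chrom={"5": 500},
            chrom_lengths={"5": 10**7},
            noise_sd=0.0,
            detp_fail_frac=0.0,
            planted_dmps=(PlantedEffect(delta=0.3, n_probes=10),
                          PlantedEffect(delta=-0.3, n_probes=10)),
            seed=21,
        )
        manifest = generate_manifest(config)
        data, truth = generate_pools(manifest, config)
        calls = call_dmps(data, manifest, threshold=0.20)
        assert {c.probe_id for c in calls} == set(truth["probe_id"])
        by_id = {c.probe_id: c for c in calls}
        for row in truth.itertuples(index=False):
            assert by_id[row.probe_id].delta_me == pytest.approx(row.delta)

    def test_threshold_monotonicity(self, tiny_manifest, tiny_pools):
        low = call_dmps(tiny_pools, tiny_manifest, threshold=0.1)
        high = call_dmps(tiny_pools, tiny_manifest, threshold=0.3)
        assert len(high) <= len(low)
        assert {c.probe_id for c in high} <= {c.probe_id for c in low}

    def test_direction_inconsistency_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DmpCall(probe_id="a", delta_me=0.3, direction=Direction.HYPO,
                    chrom="1", pos=1)


class TestGlobalSummary:
    def test_identical_pools(self):
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.2, 0.8, 50)
        data = pools([f"p{i}" for i in range(50)], beta, beta.copy())
        summary = global_summary(data)
        assert summary.t_statistic == pytest.approx(0.0)
        assert summary.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_pools_degenerate(self):
        data = pools(["a", "b"], [0.5, 0.5], [0.5, 0.5])
        summary = global_summary(data)
        assert (summary.t_statistic, summary.p_value) == (0.0, 1.0)

    def test_clearly_shifted_pools(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.4, 200)
        data = pools([f"p{i}" for i in range(200)], base, base + 0.4)
        summary = global_summary(data)
        assert summary.p_value < 1e-10
        assert summary.mean_female > summary.mean_male


class TestRegionDistribution:
    def test_single_group_fraction_one(self):
        calls = [make_call(f"p{i}", 0.3, [("A", "Body")]) for i in range(3)]
        table = region_distribution(calls).set_index("region_group")
        assert table.loc["Body", "count"] == 3
        assert table.loc["Body", "fraction"] == 1.0

    def test_same_group_via_two_genes_counts_once(self):
        calls = [make_call("p1", 0.3, [("A", "Body"), ("B", "Body")])]
        table = region_distribution(calls).set_index("region_group")
        assert table.loc["Body", "count"] == 1

    def test_multi_region_probe_counts_in_each_group(self):
        calls = [make_call("p1", 0.3, [("A", "Body"), ("A", "TSS200")])]
        table = region_distribution(calls).set_index("region_group")
        assert table.loc["Body", "count"] == 1
        assert table.loc["TSS200", "count"] == 1
        assert table.loc["Body", "fraction"] == 0.5

    def test_intergenic_bucket_excluded_from_fractions(self):
        calls = [
            make_call("p1", 0.3, [("A", "Body")]),
            make_call("p2", 0.3),
        ]
        table = region_distribution(calls).set_index("region_group")
        assert table.loc["intergenic", "count"] == 1
        assert table.loc["Body", "fraction"] == 1.0
        genic = table.drop("intergenic")
        assert genic["fraction"].sum() == pytest.approx(1.0)


class TestWindowCounts:
    layout = GenomeLayout(chrom_lengths={"1": 25_000_000}, window_size=10**7)

    def test_half_open_window_boundary(self):
        probes = [ann("a", "1", 10_000_000), ann("b", "1", 10_000_001)]
        table = window_counts(probes, self.layout)
        counts = dict(zip(table["window_index"], table["count"]))
        assert counts == {0: 1, 1: 1, 2: 0}

    def test_emits_all_windows_including_short_last(self):
        table = window_counts([ann("a", "1", 5)], self.layout)
        assert list(table["window_index"]) == [0, 1, 2]
        assert table["count"].sum() == 1

    def test_position_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            window_counts([ann("a", "1", 30_000_000)], self.layout)

    def test_counts_conserve_probes_and_means_use_members(self):
        probes = [ann(f"p{i}", "1", 1 + i * 4_000_000) for i in range(6)]
        betas = {p.probe_id: (0.2, 0.4) for p in probes}
        table = window_counts(probes, self.layout, beta_by_probe=betas)
        assert table["count"].sum() == 6
        occupied = table[table["count"] > 0]
        assert occupied["mean_beta_male"].to_numpy() == pytest.approx(0.2)
        assert occupied["mean_beta_female"].to_numpy() == pytest.approx(0.4)
        assert table[table["count"] == 0]["mean_beta_male"].isna().all()

    def test_uniform_probes_within_poisson_bounds(self):
        config = SimulationConfig(
            n_probes_per_chrom={"1": 2000},
            chrom_lengths={"1": 100_000_000},
            seed=13,
        )
        manifest = generate_manifest(config)
        table = window_counts(manifest, GenomeLayout(
            chrom_lengths={"1": 100_000_000}))
        expected = 200  # 2000 probes over 10 windows
        # 99% Poisson interval per window
        lo, hi = expected - 2.58 * np.sqrt(expected), expected + 2.58 * np.sqrt(expected)
        assert ((table["count"] >= lo) & (table["count"] <= hi)).mean() >= 0.8


class TestDirectionSplit:
    def test_all_hyper(self):
        split = direction_split([make_call(f"p{i}", 0.3) for i in range(4)])
        assert (split.n_hyper, split.n_hypo) == (4, 0)
        assert split.hyper_fraction == 1.0

    def test_symmetric_split_and_per_region(self):
        calls = [
            make_call("p1", 0.3, [("A", "Body")]),
            make_call("p2", -0.3, [("B", "Body")]),
        ]
        split = direction_split(calls)
        assert split.n_hyper == split.n_hypo == 1
        body = split.per_region.set_index("region_group").loc["Body"]
        assert (body["n_hyper"], body["n_hypo"]) == (1, 1)

    def test_empty_call_set_degenerate(self):
        split = direction_split([])
        assert split.total == 0
        assert np.isnan(split.hyper_fraction)


class TestXHypomethylation:
    manifest = [
        ann("x_down", "X", 100, [("AR", "Body")]),
        ann("x_up", "X", 200, [("AR", "TSS200")]),
        ann("y_down", "Y", 100),
        ann("auto_down", "7", 100),
    ]

    def test_only_chrx_hypomethylation_called(self):
        data = pools(
            ["x_down", "x_up", "y_down", "auto_down"],
            [0.8, 0.2, 0.8, 0.9],
            [0.5, 0.5, 0.5, 0.6],
        )
        calls = x_hypomethylation_analysis(data, annotations_by_probe(self.manifest))
        assert [c.probe_id for c in calls] == ["x_down"]
        assert calls[0].direction is Direction.HYPO

    def test_no_chrx_probes_warns_and_returns_empty(self, caplog):
        data = pools(["auto_down"], [0.9], [0.5])
        calls = x_hypomethylation_analysis(
            data, annotations_by_probe(self.manifest)
        )
        assert calls == []
        assert any("chrX" in r.message for r in caplog.records)

    def test_detection_p_qc_applied(self):
        data = pools(["x_down"], [0.8], [0.5], detp=0.2)
        assert x_hypomethylation_analysis(
            data, annotations_by_probe(self.manifest)
        ) == []


def test_percent_formatting_three_significant_figures():
    assert percent_of_probes(1, 3) == "33.3"
    assert percent_of_probes(0, 100) == "0"
    with pytest.raises(ValueError):
        percent_of_probes(1, 0)
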