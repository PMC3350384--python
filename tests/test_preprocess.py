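import dataclasses
import random

import numpy as np
import pandas as pd
import pytest

from anchorcorr import (
    DatasetMetadata,
    ExpressionDataset,
    ProbeGeneMap,
    collapse_probes,
    example_screening_metadata,
    group_log2_ratio,
    screen_datasets,
    to_log2,
)
from anchorcorr.preprocess import median_center


def _meta(dataset_id="d1", **kwargs):
    return DatasetMetadata(dataset_id=dataset_id, n_samples=10, **kwargs)


class TestScreening:
    def test_missing_anchor_probe_is_reason_2(self):
        report = screen_datasets([_meta(has_anchor_probe=False)])
        assert report.excluded == [("d1", 2)]

    def test_all_predicates_satisfied_included(self):
        report = screen_datasets([_meta()])
        assert report.included == ["d1"]
        assert report.excluded == []

    @pytest.mark.parametrize(
        "field,bad,code",
        [
            ("has_control_samples", False, 1),
            ("has_anchor_probe", False, 2),
            ("has_publication", False, 3),
            ("is_time_course", True, 4),
            ("has_hgnc_symbols", False, 5),
            ("has_anchor_data", False, 6),
        ],
    )
    def test_each_rule_fires_with_its_code(self, field, bad, code):
        report = screen_datasets([_meta(**{field: bad})])
        assert report.excluded == [("d1", code)]

    def test_lowest_numbered_rule_wins(self):
        meta = _meta(has_publication=False, has_hgnc_symbols=False)
        assert screen_datasets([meta]).excluded == [("d1", 3)]

    def test_engineered_49_collection_yields_23(self):
        metas = example_screening_metadata()
        assert len(metas) == 49
        report = screen_datasets(metas)
        assert report.n_included == 23
        assert len(report.excluded) == 26

    def test_order_independent_and_idempotent(self):
        metas = example_screening_metadata()
        shuffled = metas[:]
        random.Random(1).shuffle(shuffled)
        a = screen_datasets(metas)
        b = screen_datasets(shuffled)
        assert a.included == b.included
        assert a.excluded == b.excluded

    def test_duplicate_dataset_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            screen_datasets([_meta(), _meta()])


def _probe_dataset(values, probes, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values[0]))]
    classes = {s: ("cancer" if i % 2 == 0 else "normal") for i, s in enumerate(samples)}
    return ExpressionDataset(
        metadata=DatasetMetadata(dataset_id="pd", n_samples=len(samples)),
        values=pd.DataFrame(values, index=probes, columns=samples),
        sample_class=classes,
        is_log2=True,
    )


class TestCollapseProbes:
    def test_max_mean_probe_kept(self):
        ds = _probe_dataset([[5.0, 5.0], [7.0, 7.0]], ["pA", "pB"])
        pmap = ProbeGeneMap({"pA": "GENEA", "pB": "GENEA"})
        out = collapse_probes(ds, pmap)
        assert out.feature_ids == ["GENEA"]
        assert out.values.loc["GENEA"].tolist() == [7.0, 7.0]

    def test_unique_probes_values_unchanged(self):
        ds = _probe_dataset([[1.0, 2.0], [3.0, 4.0]], ["p1", "p2"])
        pmap = ProbeGeneMap({"p1": "GA", "p2": "GB"})
        out = collapse_probes(ds, pmap)
        assert sorted(out.feature_ids) == ["GA", "GB"]
        assert out.values.loc["GA"].tolist() == [1.0, 2.0]

    def test_mean_tie_broken_by_smallest_probe_id(self):
        ds = _probe_dataset([[2.0, 4.0], [4.0, 2.0]], ["pB", "pA"])
        pmap = ProbeGeneMap({"pA": "G", "pB": "G"})
        out = collapse_probes(ds, pmap)
        assert out.values.loc["G"].tolist() == [4.0, 2.0]  # from pA

    def test_unmapped_probes_dropped(self):
        ds = _probe_dataset([[1.0, 1.0], [2.0, 2.0]], ["p1", "px"])
        out = collapse_probes(ds, ProbeGeneMap({"p1": "GA"}))
        assert out.feature_ids == ["GA"]

    def test_anchor_missing_after_collapse_is_hard_error(self):
        ds = _probe_dataset([[1.0, 1.0]], ["p1"])
        with pytest.raises(ValueError, match="PSME3.*absent"):
            collapse_probes(ds, ProbeGeneMap({"p1": "GA"}), anchor_symbol="PSME3")


class TestLog2:
    def test_mono_channel_log2(self):
        ds = _probe_dataset([[8.0, 2.0]], ["g1"])
        ds.is_log2 = False
        out = to_log2(ds)
        assert out.values.loc["g1"].tolist() == [3.0, 1.0]
        assert out.is_log2

    def test_two_channel_passthrough(self):
        meta = DatasetMetadata(dataset_id="tc", channel="two_channel", n_samples=2)
        ds = ExpressionDataset(
            metadata=meta,
            values=pd.DataFrame([[-1.5, 0.5]], index=["g1"], columns=["s1", "s2"]),
            sample_class={"s1": "cancer", "s2": "normal"},
            is_log2=True,
        )
        out = to_log2(ds)
        assert out.values.equals(ds.values)

    def test_non_positive_values_clipped_to_floor(self):
        ds = _probe_dataset([[0.0, 4.0]], ["g1"])
        ds.is_log2 = False
        out = to_log2(ds, floor=1e-3)
        assert out.values.loc["g1", "s0"] == pytest.approx(np.log2(1e-3))
        assert out.values.loc["g1", "s1"] == 2.0

    def test_collapse_and_log2_commute_on_positive_data(self, rng):
        values = rng.uniform(0.5, 100.0, size=(6, 4))
        probes = [f"p{i}" for i in range(6)]
        pmap = ProbeGeneMap({p: f"G{i // 2}" for i, p in enumerate(probes)})
        ds = _probe_dataset(values, probes)
        ds.is_log2 = False
        a = to_log2(collapse_probes(ds, pmap))
        b = collapse_probes(to_log2(ds), pmap)
        pd.testing.assert_frame_equal(
            a.values.sort_index(), b.values.sort_index(), check_exact=False
        )

    def test_median_center_requires_log2(self):
        ds = _probe_dataset([[1.0, 2.0]], ["g1"])
        ds.is_log2 = False
        with pytest.raises(ValueError):
            median_center(ds)
        centered = median_center(to_log2(ds))
        assert (centered.values.median(axis=0) == 0).all()


class TestGroupRatio:
    def test_identical_group_means_give_zero(self):
        ds = _probe_dataset([[2.0, 2.0, 2.0, 2.0]], ["g1"])
        assert group_log2_ratio(ds, "cancer", "normal").loc["g1"] == 0.0

    def test_fold_1_25_worked_example(self):
        ds = _probe_dataset([[4.321928, 4.321928, 4.0, 4.0]], ["g1"],
                            samples=["c1", "c2", "n1", "n2"])
        ds.sample_class = {"c1": "cancer", "c2": "cancer", "n1": "normal", "n2": "normal"}
        ratio = group_log2_ratio(ds, "cancer", "normal").loc["g1"]
        assert ratio == pytest.approx(np.log2(1.25), abs=1e-6)

    def test_empty_class_rejected(self):
        ds = _probe_dataset([[1.0, 2.0]], ["g1"])
        with pytest.raises(ValueError, match="disease"):
            group_log2_ratio(ds, "cancer", "disease")

    def test_planted_anchor_fold_recovered(self):
        from anchorcorr import SimulationConfig, simulate_dataset

        config = SimulationConfig(
            n_genes=0, anchor_fold_change=2.43, noise_sd=0.5,
            n_samples={"cancer": 100, "disease": 0, "normal": 100},
            output_scale="log2", seed=17,
        )
        ds, _ = simulate_dataset(config, dataset_id="fc01")
        ratio = group_log2_ratio(ds, "cancer", "normal").loc["PSME3"]
        # SE = 0.5 * sqrt(2/100) ~= 0.0707; allow ~3.5 SE
        assert ratio == pytest.approx(np.log2(2.43), abs=0.25)
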