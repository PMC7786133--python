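import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import guildnet as gn
from guildnet.data import (
    CommunityTableError,
    back_transform_abundance,
    validate_metadata,
)


def _write_table(tmp_path, rows, samples=None, otus=None, name="t.tsv"):
    samples = samples or [f"s{i}" for i in range(len(rows))]
    otus = otus or [f"o{j}" for j in range(len(rows[0]))]
    df = pd.DataFrame(rows, index=samples, columns=otus)
    path = tmp_path / name
    df.to_csv(path, sep="\t")
    return path


class TestReadCommunityTable:
    def test_depth_is_row_sum(self, tmp_path):
        path = _write_table(tmp_path, [[3, 0], [1, 5]])
        t = gn.read_community_table(path, "fungi")
        assert list(t.depth) == [3, 6]
        assert t.n_samples == 2

    def test_negative_cell_names_location(self, tmp_path):
        path = _write_table(tmp_path, [[3, -1], [1, 5]])
        with pytest.raises(CommunityTableError, match=r"s0.*o1"):
            gn.read_community_table(path, "fungi")

    def test_non_integer_cell_rejected(self, tmp_path):
        path = _write_table(tmp_path, [[3, 1.5], [1, 5]])
        with pytest.raises(CommunityTableError, match="non-integer"):
            gn.read_community_table(path, "fungi")

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = _write_table(tmp_path, [[1, 2], [3, 4]], samples=["a", "a"])
        with pytest.raises(CommunityTableError, match="duplicated sample"):
            gn.read_community_table(path, "fungi")

    def test_transposed_reader(self, tmp_path):
        path = _write_table(tmp_path, [[3, 0], [1, 5]])
        t = gn.read_community_table(path, "fungi", transposed=True)
        assert t.counts.shape == (2, 2)
        assert list(t.depth) == [4, 5]

    def test_unknown_guild_rejected(self, tmp_path):
        path = _write_table(tmp_path, [[1, 0], [0, 1]])
        with pytest.raises(CommunityTableError, match="guild"):
            gn.read_community_table(path, "archaea")


class TestFilterOtus:
    @pytest.fixture
    def toy(self):
        # 10 samples; A: 1 presence at 50% rel abund; B: 3 presences, max rel
        # abund 0.004; C: 5 presences, high rel abund
        counts = np.zeros((10, 3), int)
        counts[0, 0] = 1000
        counts[:3, 1] = 8
        counts[:5, 2] = 600
        depth_fill = 2000 - counts.sum(axis=1)
        counts = np.column_stack([counts, depth_fill])  # filler OTU to fix depths
        return gn.CommunityTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(10)],
                         columns=["A", "B", "C", "fill"]),
            guild="fungi",
        )

    def test_prevalence_strictly_greater(self, toy):
        kept = gn.filter_otus(toy, gn.FilterSpec(0.10, 0.005)).otu_ids
        assert "A" not in kept  # prevalence exactly 0.10 is not > 0.10
        assert "C" in kept

    def test_relabund_threshold_inclusive(self, toy):
        kept = gn.filter_otus(toy, gn.FilterSpec(0.10, 0.005)).otu_ids
        assert "B" not in kept  # max relative abundance 0.004 < 0.005

    def test_zero_thresholds_keep_everything(self, toy):
        kept = gn.filter_otus(toy, gn.FilterSpec(0.0, 0.0))
        assert list(kept.otu_ids) == list(toy.otu_ids)

    def test_all_removed_raises(self):
        # every OTU occurs in exactly one sample: nothing survives a 50% screen
        t = gn.CommunityTable(pd.DataFrame(np.eye(10, dtype=int) * 5), guild="fungi")
        with pytest.raises(CommunityTableError, match="relax"):
            gn.filter_otus(t, gn.FilterSpec(0.5, 0.9))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.6), st.floats(0.0, 0.3))
    def test_idempotent_and_monotone(self, seed, prev, relab):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, size=(8, 6))
        counts[:, 0] += 1  # never empty
        t = gn.CommunityTable(pd.DataFrame(counts), guild="bacteria")
        spec = gn.FilterSpec(prev, relab)
        once = gn.filter_otus(t, spec)
        twice = gn.filter_otus(once, spec)
        assert list(once.otu_ids) == list(twice.otu_ids)
        looser = gn.filter_otus(t, gn.FilterSpec(prev / 2, relab / 2))
        assert set(once.otu_ids) <= set(looser.otu_ids)


class TestDesignMatrix:
    def test_null_design_is_depth_only(self, small_study):
        dm = gn.build_design_matrix(small_study.metadata, "null", "fungi")
        assert dm.column_names == ["intercept", "log_reads_fungi"]
        assert dm.group_map["log_reads_fungi"] == "depth"

    def test_full_design_columns_and_groups(self, small_study):
        dm = gn.build_design_matrix(small_study.metadata, "full", "bacteria")
        assert len(dm.column_names) == 13
        groups = pd.Series(dm.group_map)
        assert (groups == "chemical").sum() == 5
        assert (groups == "physical").sum() == 6
        assert (groups == "depth").sum() == 1
        assert dm.reference_levels == {"tree_species": "beech", "decay_class": "<5"}

    def test_joint_design_has_one_depth_column_per_guild(self, small_study):
        dm = gn.build_joint_design(small_study.metadata, "full")
        assert len(dm.column_names) == 14
        assert {"log_reads_fungi", "log_reads_bacteria"} <= set(dm.column_names)
        dm0 = gn.build_joint_design(small_study.metadata, "null")
        assert len(dm0.column_names) == 3

    def test_cn_ratio_column_dropped(self, small_study, caplog):
        meta = small_study.metadata.copy()
        meta["cn_ratio"] = meta["c"] / meta["n"]
        with caplog.at_level("INFO", logger="guildnet"):
            out = validate_metadata(meta)
        assert "cn_ratio" not in out.columns
        assert any("C/N" in rec.message for rec in caplog.records)

    def test_nonpositive_nitrogen_rejected(self, small_study):
        meta = small_study.metadata.copy()
        meta.loc[meta.index[0], "n"] = 0.0
        with pytest.raises(ValueError, match="N content"):
            gn.build_design_matrix(meta, "full", "fungi")

    def test_nonpositive_reads_rejected(self, small_study):
        meta = small_study.metadata.copy()
        meta.loc[meta.index[0], "reads_fungi"] = 0
        with pytest.raises(ValueError, match="reads_fungi"):
            gn.build_design_matrix(meta, "null", "fungi")


class TestHurdleResponse:
    def test_two_presence_standardization(self):
        t = gn.CommunityTable(pd.DataFrame({"x": [0, 4, 8], "y": [1, 1, 1]}), "fungi")
        resp = gn.assemble_hurdle_response(t)
        assert list(resp.pa["x"]) == [0, 1, 1]
        vals = resp.abund["x"].dropna().to_numpy()
        assert np.allclose(sorted(vals), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_all_zero_otu_rejected(self):
        t = gn.CommunityTable(pd.DataFrame({"x": [0, 0, 0], "y": [1, 2, 1]}), "fungi")
        with pytest.raises(CommunityTableError, match="no presences"):
            gn.assemble_hurdle_response(t)

    def test_constant_counts_flagged_degenerate(self):
        t = gn.CommunityTable(pd.DataFrame({"x": [5, 5, 5, 0], "y": [1, 2, 3, 4]}), "fungi")
        resp = gn.assemble_hurdle_response(t)
        assert bool(resp.degenerate["x"])
        assert not bool(resp.degenerate["y"])
        assert np.allclose(resp.abund["x"].dropna(), 0.0)

    def test_back_transform_recovers_log_counts(self, small_study):
        t = small_study.tables["fungi"]
        resp = gn.assemble_hurdle_response(t)
        recovered = back_transform_abundance(resp)
        logc = np.log(t.counts.to_numpy(float), where=t.counts.to_numpy() > 0,
                      out=np.full(t.counts.shape, np.nan))
        ok = ~resp.degenerate.to_numpy()
        assert np.allclose(recovered.to_numpy()[:, ok], logc[:, ok], equal_nan=True)

    def test_concat_keeps_guild_labels(self, small_response):
        assert set(small_response.guild) == {"fungi", "bacteria"}
        assert small_response.n_otus == 24
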