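import logging

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retest import (
    InputError,
    SeedPairIndex,
    fisher_z,
    fisher_z_matrix,
    load_feature_table,
    load_label_volume_pair,
    seedpair_matrix,
    seedpair_vector,
)

WIDE = """subject,session,volA,volB
s1,test,1.0,10.0
s1,retest,1.1,10.5
s2,test,2.0,20.0
s2,retest,2.1,19.5
s3,test,3.0,30.0
s3,retest,2.9,30.5
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadFeatureTable:
    def test_wide_layout(self, tmp_path):
        t = load_feature_table(_write(tmp_path, "w.csv", WIDE), layout="wide")
        assert t.n_subjects == 3 and t.n_features == 2
        assert t.subject_ids == ["s1", "s2", "s3"]
        assert t.feature_names == ["volA", "volB"]
        assert t.session("test")[0, 0] == 1.0
        assert t.session("retest")[2, 1] == 30.5

    def test_long_layout_matches_wide(self, tmp_path):
        wide = load_feature_table(_write(tmp_path, "w.csv", WIDE), layout="wide")
        long_csv = "subject,session,feature,value\n" + "".join(
            f"{s},{sess},{f},{wide.values[i, j, r]:.17g}\n"
            for i, s in enumerate(wide.subject_ids)
            for j, sess in enumerate(wide.session_labels)
            for r, f in enumerate(wide.feature_names)
        )
        t = load_feature_table(_write(tmp_path, "l.csv", long_csv), layout="long")
        assert t == wide

    def test_incomplete_subject_excluded_with_warning(self, tmp_path, caplog):
        text = WIDE + "s4,test,4.0,40.0\n"
        with caplog.at_level(logging.WARNING, logger="retest"):
            t = load_feature_table(_write(tmp_path, "w.csv", text))
        assert t.n_subjects == 3
        assert "s4" not in t.subject_ids
        assert any("excluded" in rec.message for rec in caplog.records)

    def test_duplicate_rows_hard_error(self, tmp_path):
        text = WIDE + "s1,test,9.0,9.0\n"
        with pytest.raises(InputError, match="duplicate"):
            load_feature_table(_write(tmp_path, "w.csv", text))

    def test_non_numeric_value_names_location(self, tmp_path):
        text = WIDE.replace("2.1,19.5", "oops,19.5")
        with pytest.raises(InputError, match="oops"):
            load_feature_table(_write(tmp_path, "w.csv", text))

    def test_strict_mode_rejects_negative_volumes(self, tmp_path):
        text = WIDE.replace("1.0,10.0", "-1.0,10.0")
        p = _write(tmp_path, "w.csv", text)
        load_feature_table(p, modality="volume")  # lenient is fine
        with pytest.raises(InputError, match="positive"):
            load_feature_table(p, modality="volume", strict=True)

    def test_write_load_roundtrip_bit_exact(self, tmp_path, table_factory):
        table, _ = table_factory(n_subjects=6, n_features=4, seed=3)
        for layout in ("wide", "long"):
            p = tmp_path / f"rt_{layout}.csv"
            table.write_csv(p, layout=layout)
            back = load_feature_table(p, layout=layout)
            assert np.array_equal(back.values, table.values)

    def test_balanced_invariant(self, tmp_path):
        t = load_feature_table(_write(tmp_path, "w.csv", WIDE))
        assert t.values.shape == (t.n_subjects, 2, t.n_features)


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        # atanh(1/2) = ln(3)/2
        assert fisher_z(0.5) == pytest.approx(np.log(3.0) / 2.0, abs=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_out_of_range_names_position(self):
        with pytest.raises(InputError, match=r"\(1,\)"):
            fisher_z(np.array([0.5, 1.0]))

    def test_matrix_variant_ignores_unit_diagonal(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = fisher_z_matrix(corr)
        assert z[0, 0] == 0.0
        assert z[0, 1] == pytest.approx(np.arctanh(0.5))


class TestSeedPairs:
    def test_three_seeds(self):
        idx = SeedPairIndex(["A", "B", "C"])
        m = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        v = seedpair_vector(m, idx)
        assert np.allclose(v, [0.2, 0.4, 0.6])
        assert idx.pair_names() == ["A~B", "A~C", "B~C"]

    def test_54_seeds_gives_1431_pairs(self):
        idx = SeedPairIndex([f"seed{k}" for k in range(54)])
        assert idx.n_pairs == 1431

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 10_000))
    def test_pack_unpack_roundtrip(self, s, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(s, s))
        m = (a + a.T) / 2.0
        np.fill_diagonal(m, 0.0)
        idx = SeedPairIndex([f"x{k}" for k in range(s)])
        assert np.array_equal(seedpair_matrix(seedpair_vector(m, idx), idx), m)

    def test_asymmetry_rejected(self):
        idx = SeedPairIndex(["A", "B"])
        with pytest.raises(InputError, match="asymmetric"):
            seedpair_vector(np.array([[0.0, 0.2], [0.4, 0.0]]), idx)


class TestLabelVolumes:
    def _save(self, path, data, dtype=np.int16):
        nib.save(nib.Nifti1Image(data.astype(dtype), np.eye(4)), str(path))

    def test_identical_files(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[1:3, 1:3, 1:3] = 2
        self._save(tmp_path / "a.nii.gz", data)
        self._save(tmp_path / "b.nii.gz", data)
        pair = load_label_volume_pair(tmp_path / "a.nii.gz", tmp_path / "b.nii.gz")
        assert np.array_equal(pair.volume_a, pair.volume_b)

    def test_fractional_values_rejected(self, tmp_path):
        self._save(tmp_path / "a.nii.gz", np.full((3, 3, 3), 0.5), dtype=np.float32)
        self._save(tmp_path / "b.nii.gz", np.ones((3, 3, 3)))
        with pytest.raises(InputError, match="non-integer"):
            load_label_volume_pair(tmp_path / "a.nii.gz", tmp_path / "b.nii.gz")

    def test_shape_mismatch_rejected(self, tmp_path):
        self._save(tmp_path / "a.nii.gz", np.ones((3, 3, 3)))
        self._save(tmp_path / "b.nii.gz", np.ones((4, 3, 3)))
        with pytest.raises(InputError, match="shapes differ"):
            load_label_volume_pair(tmp_path / "a.nii.gz", tmp_path / "b.nii.gz")
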