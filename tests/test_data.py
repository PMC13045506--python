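"""Metadata pipeline, split semantics, augmentation contracts and the
synthetic generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from wheatstage.data import (
    AugmentConfig,
    DEFAULT_STAGE_MAP,
    SampleRecord,
    SchemaError,
    StageMap,
    augment,
    filter_expert,
    load_image,
    load_metadata,
    nearest_centroid_accuracy,
    remap_stage,
    save_image,
    stratified_split,
    synth_arrays,
    synth_dataset,
    trapezoid_mask,
)


def write_csv(tmp_path, rows, columns=("image_id", "stage", "label_quality")):
    path = tmp_path / "Train.csv"
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


# -- metadata ------------------------------------------------------------------

def test_load_metadata_toy_csv(tmp_path):
    rows = [(f"img{i}", s, q) for i, (s, q) in
            enumerate(zip([2, 3, 4, 5, 7, 2], [2, 1, 2, 2, 1, 2]))]
    records, rejects = load_metadata(write_csv(tmp_path, rows))
    assert len(records) == 6 and not rejects
    assert records[0].image_id == "img0" and records[0].label_quality == 2


def test_load_metadata_rejects_stage_out_of_range(tmp_path):
    records, rejects = load_metadata(
        write_csv(tmp_path, [("a", 2, 2), ("b", 9, 2)]))
    assert len(records) == 1
    assert rejects[0]["reason"] == "stage out of range"


def test_load_metadata_missing_column_is_schema_error(tmp_path):
    path = tmp_path / "Train.csv"
    pd.DataFrame([("a", 2)], columns=["image_id", "stage"]).to_csv(
        path, index=False)
    with pytest.raises(SchemaError, match="label_quality"):
        load_metadata(path)


def test_load_metadata_empty_file_warns(tmp_path):
    path = tmp_path / "Train.csv"
    path.write_text("")
    with pytest.warns(UserWarning):
        records, rejects = load_metadata(path)
    assert records == [] and rejects == []


def test_filter_expert_keeps_quality2_only(tmp_path):
    rows = [(f"i{i}", s, q) for i, (s, q) in
            enumerate(zip([2, 3, 4, 5, 7, 2], [2, 1, 2, 2, 1, 2]))]
    records, _ = load_metadata(write_csv(tmp_path, rows))
    experts = filter_expert(records)
    assert len(experts) == 4
    assert all(r.label_quality == 2 for r in experts)


def test_filter_expert_all_farmer_warns():
    records = [SampleRecord("a", 2, 1), SampleRecord("b", 3, 1)]
    with pytest.warns(UserWarning):
        assert filter_expert(records) == []


def test_filter_expert_stage6_contract_violation():
    with pytest.raises(ValueError, match="absent from expert subset"):
        filter_expert([SampleRecord("a", 6, 2)])


# -- stage remapping -----------------------------------------------------------

@pytest.mark.parametrize("stage,index", [(2, 0), (3, 1), (4, 2), (5, 3), (7, 4)])
def test_remap_retained_stages(stage, index):
    assert remap_stage(stage) == index
    assert DEFAULT_STAGE_MAP.to_stage(index) == stage


@pytest.mark.parametrize("stage", [1, 6, 8])
def test_remap_rejects_non_retained_stage(stage):
    with pytest.raises(ValueError):
        remap_stage(stage)


def test_stage_map_is_bijective():
    m = StageMap()
    assert [m.to_index(m.to_stage(i)) for i in range(5)] == list(range(5))
    assert m.display_name(0) == "Tillering" and m.display_name(4) == "Milking"


# -- splitting -----------------------------------------------------------------

def _records(sizes: dict[int, int]):
    return [SampleRecord(f"s{stage}_{i}", stage, 2)
            for stage, n in sizes.items() for i in range(n)]


def test_split_single_class_exact_ratio():
    train, test = stratified_split(_records({2: 10}), 0.8, seed=0)
    assert (len(train), len(test)) == (8, 2)


def test_split_per_class_rounding():
    train, test = stratified_split(_records({2: 10, 3: 5}), 0.8, seed=0)
    per_class = lambda recs, s: sum(r.stage == s for r in recs)
    assert per_class(train, 2) == 8 and per_class(test, 2) == 2
    assert per_class(train, 3) == 4 and per_class(test, 3) == 1


def test_split_disjoint_exhaustive_and_deterministic():
    records = _records({2: 13, 3: 7, 4: 9})
    a_train, a_test = stratified_split(records, 0.8, seed=5)
    b_train, b_test = stratified_split(records, 0.8, seed=5)
    assert [r.image_id for r in a_train] == [r.image_id for r in b_train]
    ids = sorted(r.image_id for r in a_train + a_test)
    assert ids == sorted(r.image_id for r in records)
    c_train, _ = stratified_split(records, 0.8, seed=6)
    assert [r.image_id for r in c_train] != [r.image_id for r in a_train]
    assert len(c_train) == len(a_train)


def test_split_warns_on_singleton_class():
    with pytest.warns(UserWarning):
        train, test = stratified_split(_records({2: 1}), 0.8, seed=0)
    assert len(train) == 1 and len(test) == 0


# -- augmentation --------------------------------------------------------------

@pytest.fixture(scope="module")
def sample_image():
    x, _, _ = synth_arrays(1, size=64, seed=9, difficulty=0.25)
    return x[0]


def test_augment_identity_config_is_exact_identity(sample_image):
    out = augment(sample_image, AugmentConfig.identity(), sample_seed=3)
    assert np.array_equal(out, sample_image)


def test_augment_flip_is_involution(sample_image):
    cfg = dataclasses.replace(AugmentConfig.identity(), flip_prob=1.0)
    once = augment(sample_image, cfg, sample_seed=1)
    twice = augment(once, cfg, sample_seed=1)
    assert not np.array_equal(once, sample_image)
    assert np.array_equal(twice, sample_image)
    assert np.array_equal(once, sample_image[:, :, ::-1])


def test_augment_deterministic_and_bounded(sample_image):
    cfg = AugmentConfig(seed=21)
    outs = [augment(sample_image, cfg, sample_seed=17) for _ in range(2)]
    assert np.array_equal(outs[0], outs[1])
    assert outs[0].shape == sample_image.shape
    assert outs[0].min() >= 0.0 and outs[0].max() <= 1.0
    # different sample seeds draw different augmentations
    other = augment(sample_image, cfg, sample_seed=18)
    assert not np.array_equal(outs[0], other)


def test_augment_config_validation():
    with pytest.raises(ValueError, match="flip_prob"):
        AugmentConfig(flip_prob=1.5)
    with pytest.raises(ValueError, match="scale_range"):
        AugmentConfig(scale_range=(1.2, 0.8))


# -- synthetic generator -------------------------------------------------------

def test_synth_arrays_counts_and_labels():
    x, y, meta = synth_arrays(10, size=32, seed=0, difficulty=0.25)
    assert x.shape == (50, 3, 32, 32)
    assert np.array_equal(np.bincount(y), np.full(5, 10))
    assert sorted(meta["stage"].unique()) == [2, 3, 4, 5, 7]
    assert (meta["label_quality"] == 2).all()


def test_synth_pixels_outside_trapezoid_are_zero():
    x, _, _ = synth_arrays(2, size=48, seed=1, difficulty=1.0)
    for img in x:
        outside = img.sum(axis=0) == 0
        assert outside.any()  # the mask actually removes something
        assert np.array_equal(img[:, outside], np.zeros_like(img[:, outside]))
    corner_mask = trapezoid_mask(48, np.random.default_rng(0))
    assert not corner_mask[0, 0] and not corner_mask[0, -1]


def test_synth_noiseless_classes_separable_by_nearest_centroid():
    x, y, _ = synth_arrays(20, size=64, seed=3, difficulty=0.0)
    acc = nearest_centroid_accuracy(x[::2], y[::2], x[1::2], y[1::2])
    assert acc == 1.0


def test_synth_dataset_files_round_trip(tmp_path):
    csv = synth_dataset(tmp_path, 3, size=32, seed=0, quality1_per_stage=1)
    records, rejects = load_metadata(csv)
    assert not rejects
    assert len(records) == 15 + 7
    experts = filter_expert(records)
    assert len(experts) == 15
    quality1_stages = sorted(r.stage for r in records if r.label_quality == 1)
    assert quality1_stages == [1, 2, 3, 4, 5, 6, 7]
    img = load_image(experts[0].path, size=32)
    assert img.shape == (3, 32, 32) and 0 <= img.min() and img.max() <= 1


def test_image_save_load_letterbox(tmp_path):
    img = np.zeros((3, 20, 40), dtype=np.float32)
    img[:, :, :] = 0.5
    path = tmp_path / "wide.png"
    save_image(img, path)
    loaded = load_image(path, size=32)
    assert loaded.shape == (3, 32, 32)
    # letterboxed bands (top/bottom) are black
    assert loaded[:, :7, :].max() == 0.0
    assert loaded[:, 26:, :].max() == 0.0
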