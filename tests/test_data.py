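"""Label readers, uncertainty policies, splitting, preprocessing and the
synthetic generator."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from hrcxr.data import (
    CHESTXRAY14_CLASSES, DatasetIndex, LabelError, SyntheticSpec,
    apply_uncertainty_policy, generate_synthetic_dataset, hard_class_spec,
    preprocess, read_chestxray14_labels, read_chexpert_labels, split_dataset,
    write_synthetic_dataset,
)


# -- ChestX-ray14 dialect ---------------------------------------------------

@pytest.fixture
def cxr14_csv(tmp_path):
    rows = [
        ("img0.png", "Cardiomegaly|Effusion", "p0"),
        ("img1.png", "No Finding", "p1"),
        ("img2.png", "Hernia", "p2"),
        ("img3.png", "Atelectasis|Mass|Nodule", "p3"),
        ("img4.png", "No Finding", "p4"),
        ("img5.png", "Pneumonia", "p5"),
        ("img6.png", "Effusion", "p6"),
        ("img7.png", "No Finding", "p7"),
        ("img8.png", "Edema|Consolidation", "p8"),
        ("img9.png", "Infiltration", "p9"),
    ]
    path = tmp_path / "labels.csv"
    pd.DataFrame(rows, columns=["Image Index", "Finding Labels", "Patient ID"]
                 ).to_csv(path, index=False)
    return path


def test_chestxray14_reader_multihot_and_no_finding(cxr14_csv):
    index, labels = read_chestxray14_labels(cxr14_csv)
    assert labels.shape == (10, 14)
    row0 = labels[0]
    assert row0[CHESTXRAY14_CLASSES.index("Cardiomegaly")] == 1
    assert row0[CHESTXRAY14_CLASSES.index("Effusion")] == 1
    assert row0.sum() == 2
    assert labels[1].sum() == 0  # "No Finding" -> all-zero row
    # hand count of row sums: 2,0,1,3,0,1,1,0,2,1
    assert labels.sum(axis=1).tolist() == [2, 0, 1, 3, 0, 1, 1, 0, 2, 1]


def test_unknown_finding_is_named_in_error(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame([("a.png", "Gremlin")],
                 columns=["Image Index", "Finding Labels"]).to_csv(
        path, index=False)
    with pytest.raises(LabelError, match="Gremlin"):
        read_chestxray14_labels(path)


def test_missing_image_skipped_unless_strict(tmp_path, cxr14_csv):
    imgdir = tmp_path / "images"
    imgdir.mkdir()
    for i in range(9):  # img9 deliberately missing
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(
            imgdir / f"img{i}.png")
    with pytest.warns(UserWarning, match="img9"):
        index, labels = read_chestxray14_labels(cxr14_csv, imgdir)
    assert len(index) == 9
    with pytest.raises(FileNotFoundError):
        read_chestxray14_labels(cxr14_csv, imgdir, strict=True)


# -- CheXpert dialect -------------------------------------------------------

@pytest.fixture
def chexpert_csv(tmp_path):
    cols = ["Path", "Atelectasis", "Cardiomegaly", "Consolidation", "Edema",
            "Pleural Effusion"]
    rows = [
        ("train/patient001/study1/view1.jpg", 1, -1, 0, "", 1),
        ("train/patient002/study1/view1.jpg", -1, 0, 1, 0, ""),
        ("train/patient003/study1/view1.jpg", 0, 1, -1, 1, 0),
    ]
    path = tmp_path / "chexpert.csv"
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


@pytest.mark.parametrize("policy,expected", [("zeros", 0), ("ones", 1)])
def test_uncertain_cells_follow_policy(chexpert_csv, policy, expected):
    _, labels = read_chexpert_labels(chexpert_csv, policy)
    assert labels[0, 1] == expected  # the -1 cells
    assert labels[1, 0] == expected
    assert labels[2, 2] == expected
    assert labels[0, 3] == 0  # blank -> 0 under either policy


def test_policies_differ_in_exactly_the_uncertain_cells(chexpert_csv):
    _, zeros = read_chexpert_labels(chexpert_csv, "zeros")
    _, ones = read_chexpert_labels(chexpert_csv, "ones")
    assert int((zeros != ones).sum()) == 3


def test_policy_is_idempotent(chexpert_csv):
    _, labels = read_chexpert_labels(chexpert_csv, "ones")
    np.testing.assert_array_equal(
        apply_uncertainty_policy(labels, "ones"), labels)


def test_unknown_policy_rejected(chexpert_csv):
    with pytest.raises(LabelError, match="policy"):
        read_chexpert_labels(chexpert_csv, "maybe")


def test_five_pathology_subset(chexpert_csv):
    index, labels = read_chexpert_labels(chexpert_csv, "zeros",
                                         five_pathologies=True)
    assert labels.shape == (3, 5)
    assert index.records[0][2] == "patient001"


# -- splitting --------------------------------------------------------------

def _index_of(n, images_per_patient=1):
    records, labels = [], []
    for p in range(n // images_per_patient):
        for i in range(images_per_patient):
            records.append((f"p{p}_i{i}.png", "", f"p{p}"))
            labels.append([p % 2])
    return DatasetIndex(records, ["x"], np.array(labels))


def test_split_100_single_image_patients_is_70_20_10():
    tr, te, va = split_dataset(_index_of(100), seed=3)
    assert (len(tr), len(te), len(va)) == (70, 20, 10)
    all_paths = set(tr.paths) | set(te.paths) | set(va.paths)
    assert len(all_paths) == 100  # disjoint and exhaustive


def test_split_seed_determinism_and_sensitivity():
    a1 = split_dataset(_index_of(100), seed=5)
    a2 = split_dataset(_index_of(100), seed=5)
    b = split_dataset(_index_of(100), seed=6)
    assert a1[0].paths == a2[0].paths
    assert a1[0].paths != b[0].paths


def test_patients_never_straddle_splits():
    idx = _index_of(30, images_per_patient=3)
    parts = split_dataset(idx, seed=0)
    assert sum(len(p) for p in parts) == 30
    for patient in {r[2] for r in idx.records}:
        homes = [i for i, part in enumerate(parts)
                 if any(r[2] == patient for r in part.records)]
        assert len(homes) == 1


def test_bad_ratios_and_tiny_datasets_rejected():
    with pytest.raises(ValueError, match="ratios"):
        split_dataset(_index_of(10), ratios=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="records"):
        split_dataset(_index_of(2))


# -- preprocessing ----------------------------------------------------------

def test_preprocess_shapes_and_eval_determinism(tmp_path):
    arr = (np.linspace(0, 255, 1024 * 1024).reshape(1024, 1024)).astype(np.uint8)
    p = tmp_path / "big.png"
    Image.fromarray(arr).save(p)
    out = preprocess(p)
    assert out.shape == (3, 224, 224)
    np.testing.assert_array_equal(out, preprocess(p))  # eval mode: no RNG
    # gray replicated to 3 channels before per-channel normalization
    from hrcxr.data import IMAGENET_MEAN, IMAGENET_STD
    raw = out * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]
    np.testing.assert_allclose(raw[0], raw[1], atol=1e-6)


def test_preprocess_train_mode_seeded_replay(rng):
    arr = rng.integers(0, 255, size=(300, 300)).astype(np.uint8)
    a = preprocess(arr, train_mode=True, rng=np.random.default_rng(11))
    b = preprocess(arr, train_mode=True, rng=np.random.default_rng(11))
    c = preprocess(arr, train_mode=True, rng=np.random.default_rng(12))
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_unreadable_image_raises_io_error(tmp_path):
    bad = tmp_path / "broken.png"
    bad.write_bytes(b"not a png")
    with pytest.raises(OSError, match="broken.png"):
        preprocess(bad)


# -- synthetic generator ----------------------------------------------------

def test_generator_is_seed_deterministic():
    spec = SyntheticSpec(num_classes=6, image_size=32)
    a = generate_synthetic_dataset(spec, 50, seed=9)
    b = generate_synthetic_dataset(spec, 50, seed=9)
    np.testing.assert_array_equal(a.images, b.images)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert a.boxes == b.boxes


def test_empirical_prevalences_within_three_standard_errors():
    spec = SyntheticSpec(image_size=16)  # rendering size irrelevant here
    ds = generate_synthetic_dataset(spec, 2000, seed=4)
    emp = ds.labels.mean(axis=0)
    p = spec.prevalences
    # co-occurrence adds a bounded positive bias; allow it on the high side
    se = np.sqrt(p * (1 - p) / 2000)
    assert np.all(emp >= p - 3 * se)
    assert np.all(emp <= p + 3 * se + spec.co_occurrence / spec.num_classes)


def test_large_central_class_has_bigger_boxes_than_small_anywhere():
    spec = SyntheticSpec(
        num_classes=2, image_size=64,
        prevalences=np.array([0.5, 0.5]),
        scale_ranges=[(0.18, 0.25), (0.05, 0.08)],
        location_priors=["center", "any"],
    )
    ds = generate_synthetic_dataset(spec, 300, seed=2)
    areas = {0: [], 1: []}
    for blist in ds.boxes:
        for k, x0, y0, x1, y1 in blist:
            areas[k].append((x1 - x0) * (y1 - y0))
    assert np.mean(areas[0]) > np.mean(areas[1])


def test_generator_csv_roundtrips_through_reader(tmp_path):
    spec = SyntheticSpec(num_classes=5, image_size=24)
    ds = generate_synthetic_dataset(spec, 30, seed=1, out_dir=tmp_path)
    index, labels = read_chestxray14_labels(
        tmp_path / "labels.csv", tmp_path / "images",
        class_names=ds.class_names)
    np.testing.assert_array_equal(labels, ds.labels)
    assert len(index) == 30
    boxes = pd.read_csv(tmp_path / "boxes.csv")
    assert len(boxes) == sum(len(b) for b in ds.boxes)


def test_impossible_geometry_rejected():
    with pytest.raises(ValueError, match="scale"):
        SyntheticSpec(num_classes=2, scale_ranges=[(0.1, 0.2), (0.5, 1.5)])


def test_hard_class_spec_lowers_one_contrast():
    spec = hard_class_spec(hard_class=3, contrast=0.1)
    assert spec.contrasts[3] == pytest.approx(0.1)
    assert np.all(spec.contrasts[np.arange(14) != 3] > 0.1)
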