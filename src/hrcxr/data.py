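"""Dataset handling: label readers, uncertainty policies, splits, preprocessing
and the synthetic multi-label lesion-image generator.

Two CSV label dialects are supported.  The ChestX-ray14 style has one row per
image with pipe-separated finding names ("Cardiomegaly|Effusion"; "No
Finding" means an all-zero label row).  The CheXpert style has one column per
observation holding 1 / 0 / -1 / blank, where -1 marks an uncertain mention
that must be resolved to 0 or 1 by a stated policy before training.

The synthetic generator draws, per image, a multi-hot label from per-class
prevalences and renders one Gaussian-profile elliptical lesion per active
class on a low-frequency noise background.  Each class has its own lesion
scale range, location prior and contrast, so classes differ in size and
position the way thoracic findings do (a cardiomegaly-like class is large and
central, a nodule-like class is small and can appear anywhere).  Ground-truth
boxes are recorded for localization checks, and labels are emitted in the
ChestX-ray14 dialect so the readers are exercised end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

CHESTXRAY14_CLASSES = [
    "Atelectasis", "Cardiomegaly", "Effusion", "Infiltration", "Mass",
    "Nodule", "Pneumonia", "Pneumothorax", "Consolidation", "Edema",
    "Emphysema", "Fibrosis", "Pleural_Thickening", "Hernia",
]

CHEXPERT_FIVE = [
    "Atelectasis", "Cardiomegaly", "Consolidation", "Edema",
    "Pleural Effusion",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


class LabelError(ValueError):
    pass


@dataclass
class DatasetIndex:
    records: list[tuple[str, str, str | None]]  # (path, raw label, patient id)
    class_names: list[str]
    labels: np.ndarray | None = None  # (n, N) multi-hot

    def __len__(self):
        return len(self.records)

    @property
    def paths(self):
        return [r[0] for r in self.records]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_chestxray14_labels(csv_path, image_dir=None, class_names=None,
                            strict: bool = False):
    """Pipe-separated finding labels -> (DatasetIndex, multi-hot matrix)."""
    names = list(class_names or CHESTXRAY14_CLASSES)
    df = pd.read_csv(csv_path)
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    img_col = cols.get("image_index") or cols.get("image")
    lab_col = cols.get("finding_labels") or cols.get("findings")
    if img_col is None or lab_col is None:
        raise LabelError(
            "CSV must have image-name and findings columns "
            f"(got {list(df.columns)})"
        )
    pat_col = cols.get("patient_id")
    lookup = {n: i for i, n in enumerate(names)}
    records, rows = [], []
    for _, row in df.iterrows():
        name = str(row[img_col])
        path = str(Path(image_dir) / name) if image_dir else name
        if image_dir and not Path(path).exists():
            if strict:
                raise FileNotFoundError(path)
            warnings.warn(f"missing image file skipped: {path}")
            continue
        vec = np.zeros(len(names), dtype=np.int64)
        raw = str(row[lab_col]).strip()
        if raw and raw.lower() not in ("no finding", "nan"):
            for token in raw.split("|"):
                token = token.strip()
                if token not in lookup:
                    raise LabelError(f"unknown finding label: {token!r}")
                vec[lookup[token]] = 1
        patient = str(row[pat_col]) if pat_col is not None else None
        records.append((path, raw, patient))
        rows.append(vec)
    if len(set(r[0] for r in records)) != len(records):
        raise LabelError("duplicate image paths in label file")
    labels = np.array(rows, dtype=np.int64).reshape(len(rows), len(names))
    index = DatasetIndex(records, names, labels)
    return index, labels


def apply_uncertainty_policy(values: np.ndarray, policy: str) -> np.ndarray:
    """Resolve CheXpert ternary labels: -1 -> 0 ('zeros') or 1 ('ones');
    blanks (NaN) become 0.  Idempotent on already-binary input."""
    if policy not in ("zeros", "ones"):
        raise LabelError(f"unknown uncertainty policy {policy!r}")
    vals = np.asarray(values, dtype=np.float64).copy()
    vals[np.isnan(vals)] = 0.0
    vals[vals == -1.0] = 0.0 if policy == "zeros" else 1.0
    return vals.astype(np.int64)


def read_chexpert_labels(csv_path, policy: str, image_dir=None,
                         five_pathologies: bool = False):
    """Per-observation columns with 1/0/-1/blank -> (index, binary matrix)."""
    df = pd.read_csv(csv_path)
    path_col = next((c for c in df.columns if c.lower() == "path"), None)
    if path_col is None:
        raise LabelError("CheXpert CSV must have a 'Path' column")
    meta = {path_col, "Sex", "Age", "Frontal/Lateral", "AP/PA"}
    obs_cols = [c for c in df.columns if c not in meta]
    if five_pathologies:
        missing = [c for c in CHEXPERT_FIVE if c not in obs_cols]
        if missing:
            raise LabelError(f"missing observation columns: {missing}")
        obs_cols = list(CHEXPERT_FIVE)
    raw = df[obs_cols].to_numpy(dtype=np.float64)
    labels = apply_uncertainty_policy(raw, policy)
    records = []
    for _, row in df.iterrows():
        p = str(row[path_col])
        prefix = str(Path(image_dir) / p) if image_dir else p
        # patient id is the leading path component in CheXpert layouts
        patient = next((part for part in Path(p).parts
                        if part.startswith("patient")), None)
        records.append((prefix, "", patient))
    index = DatasetIndex(records, obs_cols, labels)
    return index, labels


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(index: DatasetIndex, ratios=(0.7, 0.2, 0.1), seed: int = 0,
                  patient_wise: bool | None = None):
    """Random train/test/val split; patients never straddle splits.

    Returns three ``DatasetIndex`` objects carrying their label slices.
    ``patient_wise`` defaults to True whenever patient ids are present.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or min(ratios) <= 0 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be 3 positives summing to 1: {ratios}")
    n = len(index)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    rng = np.random.default_rng(seed)
    has_patients = all(r[2] is not None for r in index.records)
    if patient_wise is None:
        patient_wise = has_patients
    if patient_wise and not has_patients:
        raise ValueError("patient-wise split requested but patient ids missing")

    if patient_wise:
        groups: dict[str, list[int]] = {}
        for i, (_, _, pid) in enumerate(index.records):
            groups.setdefault(pid, []).append(i)
        keys = sorted(groups)
        rng.shuffle(keys)
        order = [i for k in keys for i in groups[k]]
        sizes = np.cumsum([len(groups[k]) for k in keys])
        t1 = int(np.searchsorted(sizes, ratios[0] * n, side="left") + 1)
        t2 = int(np.searchsorted(sizes, (ratios[0] + ratios[1]) * n,
                                 side="left") + 1)
        cut1 = sizes[min(t1, len(sizes)) - 1]
        cut2 = sizes[min(max(t2, t1 + 1), len(sizes)) - 1]
        parts = (order[:cut1], order[cut1:cut2], order[cut2:])
    else:
        order = rng.permutation(n)
        c1 = int(round(ratios[0] * n))
        c2 = int(round((ratios[0] + ratios[1]) * n))
        parts = (list(order[:c1]), list(order[c1:c2]), list(order[c2:]))
    if any(len(p) == 0 for p in parts):
        raise ValueError("a split came out empty; use more records")

    def take(idxs):
        return DatasetIndex(
            [index.records[i] for i in idxs], index.class_names,
            index.labels[list(idxs)] if index.labels is not None else None,
        )

    return tuple(take(p) for p in parts)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(image, train_mode: bool = False, rng=None, resize_to: int = 256,
               crop_to: int = 224, mean=IMAGENET_MEAN, std=IMAGENET_STD):
    """Resize -> 3-channel -> crop (random in training, center otherwise)
    -> optional horizontal flip -> 0..1 scaling -> channel normalization.

    Accepts a path, PIL image, or (H,W)/(H,W,3) array; returns float32
    (3, crop_to, crop_to).
    """
    if isinstance(image, (str, Path)):
        try:
            image = Image.open(image)
        except OSError as exc:
            raise OSError(f"cannot read image {image}: {exc}") from exc
    if isinstance(image, np.ndarray):
        arr = image
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        image = Image.fromarray(arr)
    image = image.convert("RGB").resize((resize_to, resize_to),
                                        Image.Resampling.BILINEAR)
    arr = np.asarray(image, dtype=np.float32)  # (H, W, 3), 0..255
    margin = resize_to - crop_to
    if margin < 0:
        raise ValueError("crop_to larger than resize_to")
    if train_mode:
        rng = rng or np.random.default_rng()
        dx = int(rng.integers(0, margin + 1))
        dy = int(rng.integers(0, margin + 1))
        flip = bool(rng.random() < 0.5)
    else:
        dx = dy = margin // 2
        flip = False
    arr = arr[dy:dy + crop_to, dx:dx + crop_to]
    if flip:
        arr = arr[:, ::-1]
    arr = arr / np.float32(255.0)
    arr = (arr - mean) / std
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


def normalize_gray_batch(images_u8: np.ndarray, mean=IMAGENET_MEAN,
                         std=IMAGENET_STD) -> np.ndarray:
    """(B,H,W) uint8 -> (B,3,H,W) normalized float32 (no resize/crop)."""
    x = images_u8.astype(np.float32) / 255.0
    x = np.repeat(x[:, None], 3, axis=1)
    return (x - mean[None, :, None, None]) / std[None, :, None, None]


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def _default_prevalences(n: int) -> np.ndarray:
    # skewed like real finding frequencies: a few common, a long rare tail
    p = 0.30 * (0.82 ** np.arange(n))
    return np.clip(p, 0.02, 0.95)


def _default_anchors(n: int) -> list[tuple[float, float]]:
    # distinct locations per class so findings have characteristic positions
    grid = [(r, c) for r in (0.25, 0.5, 0.75) for c in (0.25, 0.5, 0.75)]
    extra = [(0.35, 0.65), (0.65, 0.35), (0.2, 0.8), (0.8, 0.2), (0.5, 0.25)]
    anchors = (grid + extra) * (n // 14 + 1)
    return anchors[:n]


@dataclass
class SyntheticSpec:
    """Study conditions for the lesion-image generator."""

    num_classes: int = 14
    image_size: int = 64
    prevalences: np.ndarray | None = None
    scale_ranges: list[tuple[float, float]] | None = None  # lesion sigma / side
    location_priors: list | None = None  # "center" | "border" | "any" | (cy,cx)
    contrasts: np.ndarray | None = None  # lesion amplitude, 0..1 gray units
    co_occurrence: float = 0.15
    noise_level: float = 0.04
    background_strength: float = 0.15

    def __post_init__(self):
        n = self.num_classes
        if self.prevalences is None:
            self.prevalences = _default_prevalences(n)
        self.prevalences = np.asarray(self.prevalences, dtype=np.float64)
        if self.scale_ranges is None:
            # alternate large/medium/small lesions across classes
            bases = [0.16, 0.10, 0.07]
            self.scale_ranges = [
                (bases[k % 3] * 0.8, bases[k % 3] * 1.25) for k in range(n)
            ]
        if self.location_priors is None:
            self.location_priors = list(_default_anchors(n))
        if self.contrasts is None:
            self.contrasts = np.full(n, 0.55)
        self.contrasts = np.asarray(self.contrasts, dtype=np.float64)
        self.validate()

    def validate(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if not np.all((self.prevalences > 0) & (self.prevalences < 1)):
            raise ValueError("prevalences must lie in (0,1)")
        for lo, hi in self.scale_ranges:
            if not 0 < lo <= hi < 1:
                raise ValueError(f"scale range ({lo},{hi}) outside (0,1)")

    def to_dict(self):
        return dict(
            num_classes=self.num_classes, image_size=self.image_size,
            prevalences=self.prevalences.tolist(),
            scale_ranges=[list(s) for s in self.scale_ranges],
            location_priors=[
                list(p) if isinstance(p, tuple) else p
                for p in self.location_priors
            ],
            contrasts=self.contrasts.tolist(),
            co_occurrence=self.co_occurrence, noise_level=self.noise_level,
            background_strength=self.background_strength,
        )


@dataclass
class SyntheticDataset:
    images: np.ndarray                 # (n, S, S) uint8
    labels: np.ndarray                 # (n, N) multi-hot
    boxes: list[list[tuple]]           # per image: (class, x0, y0, x1, y1)
    class_names: list[str]
    spec: SyntheticSpec
    patient_ids: list[str] = field(default_factory=list)

    def to_index(self) -> DatasetIndex:
        records = [
            (f"img{i:06d}.png", "", self.patient_ids[i] if self.patient_ids
             else None)
            for i in range(len(self.images))
        ]
        return DatasetIndex(records, self.class_names, self.labels)


def _lesion_center(rng, prior, size, sigma):
    m = 3.0 * sigma
    if isinstance(prior, (tuple, list)):
        cy = prior[0] * size + rng.normal(0, 0.05 * size)
        cx = prior[1] * size + rng.normal(0, 0.05 * size)
    elif prior == "center":
        cy = size / 2 + rng.normal(0, 0.08 * size)
        cx = size / 2 + rng.normal(0, 0.08 * size)
    elif prior == "border":
        edge = rng.integers(4)
        u = rng.uniform(m, size - m)
        v = rng.uniform(m, 0.25 * size)
        cy, cx = [(v, u), (size - v, u), (u, v), (u, size - v)][edge]
    elif prior == "any":
        cy = rng.uniform(m, size - m)
        cx = rng.uniform(m, size - m)
    else:
        raise ValueError(f"unknown location prior {prior!r}")
    return float(np.clip(cy, m, size - m)), float(np.clip(cx, m, size - m))


def generate_synthetic_dataset(spec: SyntheticSpec, n: int, seed: int = 0,
                               out_dir=None) -> SyntheticDataset:
    """Draw ``n`` labelled lesion images; deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    S, N = spec.image_size, spec.num_classes
    names = (CHESTXRAY14_CLASSES[:N] if N <= 14
             else [f"Finding{k}" for k in range(N)])
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    images = np.empty((n, S, S), dtype=np.uint8)
    labels = np.zeros((n, N), dtype=np.int64)
    boxes: list[list[tuple]] = []
    for i in range(n):
        active = rng.random(N) < spec.prevalences
        if active.any() and rng.random() < spec.co_occurrence:
            active[rng.integers(N)] = True
        labels[i, active] = 1
        # low-frequency background plus a vertical intensity gradient
        bg = ndimage.gaussian_filter(rng.standard_normal((S, S)), S / 8.0)
        bg = (bg - bg.min()) / (np.ptp(bg) + 1e-9) - 0.5
        img = 0.45 + spec.background_strength * bg + 0.05 * (yy / S - 0.5)
        img_boxes = []
        for k in np.flatnonzero(active):
            lo, hi = spec.scale_ranges[k]
            sigma = rng.uniform(lo, hi) * S
            cy, cx = _lesion_center(rng, spec.location_priors[k], S, sigma)
            aspect = rng.uniform(0.7, 1.4)
            sy, sx = sigma * aspect, sigma / aspect
            d2 = ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2
            img += spec.contrasts[k] * np.exp(-0.5 * d2)
            img_boxes.append((
                int(k),
                max(0, int(cx - 2 * sx)), max(0, int(cy - 2 * sy)),
                min(S, int(cx + 2 * sx) + 1), min(S, int(cy + 2 * sy) + 1),
            ))
        img += spec.noise_level * rng.standard_normal((S, S))
        images[i] = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        boxes.append(img_boxes)
    patient_ids = [f"p{i:06d}" for i in range(n)]
    ds = SyntheticDataset(images, labels, boxes, names, spec, patient_ids)
    if out_dir is not None:
        write_synthetic_dataset(ds, out_dir)
    return ds


def write_synthetic_dataset(ds: SyntheticDataset, out_dir):
    """Emit images/, labels.csv (ChestX-ray14 dialect), boxes.csv, spec.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows, box_rows = [], []
    for i, img in enumerate(ds.images):
        name = f"img{i:06d}.png"
        Image.fromarray(img).save(out / "images" / name)
        findings = [ds.class_names[k]
                    for k in np.flatnonzero(ds.labels[i])]
        rows.append(dict(
            **{"Image Index": name,
               "Finding Labels": "|".join(findings) or "No Finding",
               "Patient ID": ds.patient_ids[i] if ds.patient_ids else str(i)},
        ))
        for k, x0, y0, x1, y1 in ds.boxes[i]:
            box_rows.append(dict(image=name, finding=ds.class_names[k],
                                 x0=x0, y0=y0, x1=x1, y1=y1))
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(box_rows).to_csv(out / "boxes.csv", index=False)
    (out / "spec.json").write_text(json.dumps(ds.spec.to_dict(), indent=2))


def hard_class_spec(base: SyntheticSpec | None = None,
                    hard_class: int = 0, contrast: float = 0.12) -> SyntheticSpec:
    """A variant with one deliberately low-contrast (hard) class."""
    spec = base or SyntheticSpec()
    contrasts = spec.contrasts.copy()
    contrasts[hard_class] = contrast
    return replace(spec, contrasts=contrasts)
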