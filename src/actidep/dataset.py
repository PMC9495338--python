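"""Labeled-matrix assembly, image encoding, splitting and z-normalization.

The unit observation is the day-vector: the 1440 per-minute activity counts
of one complete calendar day, labelled by its subject's group (0 = not
depressed, 1 = depressed).  A cohort of S subjects contributes exactly 7
day-vectors each, giving the observation matrix A of shape (7*S, 1440).

Day-vectors feed the convolutional classifier as 30x48 single-channel images,
filled row-major so each image row spans 48 consecutive minutes.  The fill
order is a fixed convention: changing it silently changes the model's
receptive fields.

Normalization is the per-column z-score z = (x - mu) / sigma with population
sigma (divide by n) by default; columns with sigma == 0 map to 0.  Parameters
are fitted on the training portion only and reused on the test portion, to
avoid test-set leakage; ``scope="all"`` replicates the alternative reading
where statistics come from the full matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io import (
    MINUTES_PER_DAY,
    SubjectSeries,
    segment_complete_days,
    select_week,
)

IMAGE_HEIGHT, IMAGE_WIDTH = 30, 48


@dataclass(frozen=True)
class LabeledDataset:
    """Observation matrix ``X`` (N x 1440) with aligned binary ``y``.

    ``subject_ids`` and ``day_dates`` carry provenance per row (empty strings
    where unknown, e.g. after synthetic oversampling).
    """

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    subject_ids: tuple[str, ...] = ()
    day_dates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] != MINUTES_PER_DAY:
            raise ValueError(f"X must be (N, {MINUTES_PER_DAY}), got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("one label per row required")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if self.subject_ids and len(self.subject_ids) != len(y):
            raise ValueError("subject_ids must align with rows")
        if self.day_dates and len(self.day_dates) != len(y):
            raise ValueError("day_dates must align with rows")

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            subject_ids=tuple(self.subject_ids[i] for i in idx)
            if self.subject_ids
            else (),
            day_dates=tuple(self.day_dates[i] for i in idx) if self.day_dates else (),
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column mean and standard deviation of the fitted z-score."""

    mu: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    ddof: int = 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=np.float64)
        sigma = np.asarray(self.sigma, dtype=np.float64)
        if mu.shape != sigma.shape or mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D and aligned")
        if np.any(sigma < 0):
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


def build_matrix(cohort: Sequence[SubjectSeries]) -> LabeledDataset:
    """Assemble the observation matrix: 7 chronological day-vectors per subject.

    Subject order is preserved; each row carries its subject's group label.
    A subject with fewer than 7 complete days raises
    :class:`~actidep.io.InsufficientDataError` naming the subject.
    """
    rows, labels, ids, dates = [], [], [], []
    for series in cohort:
        week = select_week(segment_complete_days(series), series.subject_id)
        for day in week:
            rows.append(day.values)
            labels.append(series.group)
            ids.append(series.subject_id)
            dates.append(day.date.isoformat())
    return LabeledDataset(
        X=np.asarray(rows, dtype=np.float64),
        y=np.asarray(labels),
        subject_ids=tuple(ids),
        day_dates=tuple(dates),
    )


def vector_to_image(v: np.ndarray) -> np.ndarray:
    """Encode a 1440-value day-vector as a 30x48 image, row-major.

    ``image[r, c] == v[48*r + c]``; invertible via :func:`image_to_vector`.
    """
    v = np.asarray(v)
    if v.shape != (MINUTES_PER_DAY,):
        raise ValueError(f"day-vector must have length {MINUTES_PER_DAY}, got {v.shape}")
    return v.reshape(IMAGE_HEIGHT, IMAGE_WIDTH)


def image_to_vector(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.shape != (IMAGE_HEIGHT, IMAGE_WIDTH):
        raise ValueError(f"image must be {IMAGE_HEIGHT}x{IMAGE_WIDTH}, got {img.shape}")
    return img.reshape(MINUTES_PER_DAY)


def to_images(ds: LabeledDataset) -> np.ndarray:
    """Stack a dataset's rows as (N, 1, 30, 48) image tensors."""
    return ds.X.reshape(len(ds), 1, IMAGE_HEIGHT, IMAGE_WIDTH)


def _stratified_train_counts(y: np.ndarray, train_n: int) -> dict[int, int]:
    # Largest-remainder apportionment of train_n across classes, so per-class
    # proportions are preserved to within one row and the total is exact.
    classes, counts = np.unique(y, return_counts=True)
    quota = train_n * counts / len(y)
    base = np.floor(quota).astype(int)
    rem = train_n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(classes.tolist(), base.tolist()))


def split_train_test(
    ds: LabeledDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded shuffle-split into disjoint, exhaustive train/test portions.

    Train size is ``floor(train_fraction * N)`` (385 observations at 0.7 give
    the 269/116 split).  With ``stratified`` the per-class proportions are
    preserved to within one row.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(ds)
    train_n = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    if stratified:
        classes, counts = np.unique(ds.y, return_counts=True)
        if (counts == 0).any() or len(classes) < 2:
            raise ValueError("stratified split requires rows in both classes")
        per_class = _stratified_train_counts(ds.y, train_n)
        train_idx: list[int] = []
        for c in classes:
            members = np.flatnonzero(ds.y == c)
            members = rng.permutation(members)
            train_idx.extend(members[: per_class[int(c)]].tolist())
        train_idx = np.sort(np.asarray(train_idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:train_n])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return ds.take(np.flatnonzero(mask)), ds.take(np.flatnonzero(~mask))


def fit_normalizer(train: LabeledDataset, ddof: int = 0) -> NormalizationParams:
    """Fit per-column mean and (population, ``ddof=0``) standard deviation."""
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    return NormalizationParams(
        mu=train.X.mean(axis=0), sigma=train.X.std(axis=0, ddof=ddof), ddof=ddof
    )


def apply_normalizer(params: NormalizationParams, ds: LabeledDataset) -> LabeledDataset:
    """z = (x - mu) / sigma per column; columns with sigma == 0 map to 0."""
    sigma = np.where(params.sigma == 0, 1.0, params.sigma)
    Z = (ds.X - params.mu) / sigma
    Z[:, params.sigma == 0] = 0.0
    return LabeledDataset(
        X=Z, y=ds.y, subject_ids=ds.subject_ids, day_dates=ds.day_dates
    )


def normalize_split(
    train: LabeledDataset,
    test: LabeledDataset,
    scope: Literal["train_only", "all"] = "train_only",
    ddof: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, NormalizationParams]:
    """Normalize a split under either leakage convention."""
    if scope == "train_only":
        params = fit_normalizer(train, ddof=ddof)
    elif scope == "all":
        pooled = LabeledDataset(
            X=np.vstack([train.X, test.X]), y=np.concatenate([train.y, test.y])
        )
        params = fit_normalizer(pooled, ddof=ddof)
    else:
        raise ValueError(f"unknown normalize scope {scope!r}")
    return apply_normalizer(params, train), apply_normalizer(params, test), params


def save_dataset(
    ds: LabeledDataset, path: str | Path, meta: dict | None = None
) -> Path:
    """Write the dataset as an ``.npz`` container plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, X=ds.X, y=ds.y)
    sidecar = {
        "subject_ids": list(ds.subject_ids),
        "day_dates": list(ds.day_dates),
        **(meta or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_dataset(path: str | Path) -> LabeledDataset:
    path = Path(path)
    with np.load(path) as data:
        X, y = data["X"], data["y"]
    sidecar_path = path.with_suffix(".json")
    ids: tuple[str, ...] = ()
    dates: tuple[str, ...] = ()
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        ids = tuple(sidecar.get("subject_ids", ()))
        dates = tuple(sidecar.get("day_dates", ()))
    return LabeledDataset(X=X, y=y, subject_ids=ids, day_dates=dates)
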