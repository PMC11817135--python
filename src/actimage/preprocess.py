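"""Day segmentation, rescaling and the labeled day-image dataset.

One calendar day of per-minute wrist-actigraphy counts (1440 values) becomes
one 30x48 grayscale image:

* the 1440 raw counts of a complete midnight-to-midnight day are min-max
  rescaled to a target range, by default [0, 255], with the observed minimum
  and maximum of that single day (each image independently spans the full
  contrast range);
* the rescaled vector is reshaped row-major to 30 rows x 48 columns;
* at model-input time each image is z-normalized (zero mean, unit population
  standard deviation) — the stored/visualized image keeps the [0, 255] scale.

Labels follow the dataset coding: control 0, depression 1, schizophrenia 2.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Condition, SubjectSeries

logger = logging.getLogger(__name__)

DAY_MINUTES = 1440
IMAGE_SHAPE = (30, 48)

#: Column names of the flattened day layout: 00:00 ... 23:59.
MINUTE_COLUMNS = [f"{m // 60:02d}:{m % 60:02d}" for m in range(DAY_MINUTES)]


class DegenerateInputError(ValueError):
    """Raised when an operation requires a non-constant input."""


@dataclasses.dataclass
class DayWindow:
    """Exactly 1440 consecutive per-minute counts for one calendar day."""

    subject_id: str
    date: datetime.date
    values: np.ndarray
    condition: Condition | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (DAY_MINUTES,):
            raise ValueError(f"a day window holds {DAY_MINUTES} values")
        if (self.values < 0).any():
            raise ValueError("activity counts must be nonnegative")


@dataclasses.dataclass
class ScalingParams:
    """Min-max rescaling parameters.

    ``lo``/``hi`` are the target bounds (0 and 255 for image storage);
    ``source_min``/``source_max`` are the observed data bounds, filled from
    the input when left as None.
    """

    lo: float = 0.0
    hi: float = 255.0
    source_min: float | None = None
    source_max: float | None = None


@dataclasses.dataclass
class EncodedImage:
    """A 30x48 day-image with its class label."""

    pixels: np.ndarray
    label: int
    subject_id: str
    date: datetime.date

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != IMAGE_SHAPE:
            raise ValueError(f"image grid must be {IMAGE_SHAPE}")
        if self.label not in (0, 1, 2):
            raise ValueError("label must be 0, 1 or 2")


@dataclasses.dataclass
class LabeledDataset:
    """An ordered collection of labeled day-images."""

    images: list[EncodedImage]

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images], dtype=np.int64)

    @property
    def subject_ids(self) -> list[str]:
        return [im.subject_id for im in self.images]

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0, 2: 0}
        for im in self.images:
            counts[im.label] += 1
        return counts

    def pixel_array(self) -> np.ndarray:
        """Stack pixels into an (n, 30, 48) array."""
        return np.stack([im.pixels for im in self.images])

    def model_inputs(self, *, standardize: bool = True) -> np.ndarray:
        """Images as network input: (n, 30, 48, 1) float32, z-scored per image."""
        x = self.pixel_array()
        if standardize:
            flat = x.reshape(len(self), -1)
            mean = flat.mean(axis=1, keepdims=True)
            sd = flat.std(axis=1, keepdims=True)
            if (sd == 0).any():
                raise DegenerateInputError("constant image cannot be standardized")
            x = ((flat - mean) / sd).reshape(x.shape)
        return x[..., None].astype(np.float32)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.images[i] for i in indices])


@dataclasses.dataclass
class PreprocessConfig:
    """Pipeline configuration.

    ``zscore_raw`` stores z-scored raw counts instead of min-max pixels
    (the alternative normalization order); the default keeps [0, 255] images
    for storage/PNG and applies the z-score at model-input time.
    """

    lo: float = 0.0
    hi: float = 255.0
    zscore_raw: bool = False


def segment_days(series: SubjectSeries) -> list[DayWindow]:
    """Split a recording into complete midnight-to-midnight day windows.

    A day qualifies only if all 1440 minutes are present exactly once;
    incomplete or duplicated days are dropped and counted in the log.
    Nothing is imputed.
    """
    windows: list[DayWindow] = []
    dropped = 0
    s = pd.Series(series.activity, index=series.timestamps)
    for date, grp in s.groupby(s.index.date):
        minutes = grp.index.hour * 60 + grp.index.minute
        if len(grp) == DAY_MINUTES and len(np.unique(minutes)) == DAY_MINUTES:
            grp = grp.sort_index()
            windows.append(
                DayWindow(series.subject_id, date, grp.to_numpy(), series.condition)
            )
        else:
            dropped += 1
    if dropped:
        logger.info(
            "subject %s: dropped %d incomplete day(s), kept %d",
            series.subject_id,
            dropped,
            len(windows),
        )
    return windows


def minmax_rescale(values, params: ScalingParams | None = None) -> np.ndarray:
    """Min-max rescale a sequence into [lo, hi].

    Each element x_i maps to ``lo + (x_i - min(x)) * (hi - lo) / (max(x) - min(x))``,
    an order-preserving affine map whose output attains both target bounds.
    ``params.source_min``/``source_max`` are filled in place from the data when
    not supplied, so the caller can recover or reuse the observed bounds.
    """
    x = np.asarray(values, dtype=float)
    if params is None:
        params = ScalingParams()
    if params.hi <= params.lo:
        raise ValueError("target bounds require hi > lo")
    if params.source_min is None:
        params.source_min = float(x.min())
    if params.source_max is None:
        params.source_max = float(x.max())
    span = params.source_max - params.source_min
    if span <= 0:
        raise DegenerateInputError("constant input: min(x) == max(x)")
    return params.lo + (x - params.source_min) * (params.hi - params.lo) / span


def zscore(values) -> np.ndarray:
    """Standardize to zero mean and unit population standard deviation."""
    x = np.asarray(values, dtype=float)
    sd = x.std()  # population convention: divide by n
    if sd == 0:
        raise DegenerateInputError("zero standard deviation")
    return (x - x.mean()) / sd


def reshape_to_image(values) -> np.ndarray:
    """Reshape a 1440-vector to the 30x48 day-image grid, row-major."""
    x = np.asarray(values)
    if x.ndim != 1 or x.shape[0] != DAY_MINUTES:
        raise ValueError(f"expected a flat sequence of {DAY_MINUTES} values")
    return x.reshape(IMAGE_SHAPE)


def encode_window(window: DayWindow, config: PreprocessConfig | None = None) -> EncodedImage:
    """Encode one complete day as a labeled image."""
    config = config or PreprocessConfig()
    if window.condition is None:
        raise ValueError("window has no condition label")
    if config.zscore_raw:
        scaled = zscore(window.values)
    else:
        scaled = minmax_rescale(
            window.values, ScalingParams(lo=config.lo, hi=config.hi)
        )
    return EncodedImage(
        pixels=reshape_to_image(scaled),
        label=window.condition.label,
        subject_id=window.subject_id,
        date=window.date,
    )


def build_dataset(
    cohorts: Mapping[Condition | str, Iterable[SubjectSeries]],
    config: PreprocessConfig | None = None,
) -> LabeledDataset:
    """Run the full encoding pipeline over per-condition subject series.

    Every complete day of every subject becomes one labeled image.  Constant
    days (e.g. device off: min == max) cannot be rescaled and are dropped
    with a warning rather than aborting the run.
    """
    config = config or PreprocessConfig()
    images: list[EncodedImage] = []
    for cond_key, series_list in cohorts.items():
        cond = Condition(cond_key) if not isinstance(cond_key, Condition) else cond_key
        for series in series_list:
            for window in segment_days(series):
                window.condition = cond
                try:
                    images.append(encode_window(window, config))
                except DegenerateInputError:
                    logger.warning(
                        "subject %s day %s: constant values, day dropped",
                        window.subject_id,
                        window.date,
                    )
    return LabeledDataset(images)


def write_dataset_csv(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write the flattened day-image table.

    Columns: ``subject_id``, ``date``, the 1440 minute columns
    ``00:00`` ... ``23:59`` (row-major flattened pixels), and ``Output``
    (the 0/1/2 class label).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = dataset.pixel_array().reshape(len(dataset), DAY_MINUTES)
    df = pd.DataFrame(flat, columns=MINUTE_COLUMNS)
    df.insert(0, "subject_id", dataset.subject_ids)
    df.insert(1, "date", [im.date.isoformat() for im in dataset.images])
    df["Output"] = dataset.labels
    df.to_csv(path, index=False)
    return path


def read_dataset_csv(path: str | Path) -> LabeledDataset:
    """Read a flattened day-image table back into a dataset."""
    df = pd.read_csv(path)
    missing = [c for c in MINUTE_COLUMNS + ["Output"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns (first: {missing[0]!r})")
    images = []
    for i, row in df.iterrows():
        date = (
            datetime.date.fromisoformat(str(row["date"]))
            if "date" in df.columns
            else datetime.date(1970, 1, 1)
        )
        images.append(
            EncodedImage(
                pixels=reshape_to_image(row[MINUTE_COLUMNS].to_numpy(dtype=float)),
                label=int(row["Output"]),
                subject_id=str(row.get("subject_id", i)),
                date=date,
            )
        )
    return LabeledDataset(images)
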