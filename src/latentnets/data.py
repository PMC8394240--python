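"""Synthetic multi-class pulse series and UCR-style text I/O.

The generator emulates heartbeat-like datasets (e.g. ECG5000): each class has a
fixed pulse morphology — a sum of Gaussian bumps at class-specific positions and
amplitudes — corrupted by additive white Gaussian noise, with possibly imbalanced
class counts.  UCR-style files are plain text, one series per row: class label
first, then the values, tab- or comma-separated, no header; rows may differ in
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

__all__ = [
    "SimConfig",
    "TimeSeriesRecord",
    "LabeledDataset",
    "generate_series",
    "generate_dataset",
    "read_ucr",
    "write_ucr",
    "default_config",
]


@dataclass(frozen=True)
class TimeSeriesRecord:
    """One labeled univariate series."""

    values: np.ndarray
    label: int
    id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a series needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"series {self.id!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class LabeledDataset:
    """A collection of labeled series; lengths may differ between records."""

    records: tuple[TimeSeriesRecord, ...]
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("dataset must contain at least one record")
        object.__setattr__(self, "records", tuple(self.records))
        if self.class_names is not None:
            object.__setattr__(self, "class_names", tuple(self.class_names))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic pulse-series generator.

    Pulse centers are fractions of the series length in [0, 1]; ``pulse_width``
    is the Gaussian bump's standard deviation, also as a fraction of length.
    ``n_per_class`` allows imbalanced designs, mirroring real heartbeat archives
    where a few classes dominate.
    """

    n_classes: int = 3
    n_per_class: tuple[int, ...] = (60, 30, 10)
    series_length: int = 140
    pulse_centers_by_class: tuple[tuple[float, ...], ...] = (
        (0.25, 0.5),
        (0.35, 0.7),
        (0.15, 0.55, 0.85),
    )
    pulse_amplitudes_by_class: tuple[tuple[float, ...], ...] = (
        (1.0, -0.6),
        (-0.8, 1.2),
        (0.7, 0.7, -1.0),
    )
    pulse_width: float = 0.04
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        for name in ("n_per_class", "pulse_centers_by_class", "pulse_amplitudes_by_class"):
            val = tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in getattr(self, name))
            object.__setattr__(self, name, val)
            if len(val) != self.n_classes:
                raise ValueError(f"{name} must have one entry per class ({self.n_classes})")
        for c, (cs, am) in enumerate(zip(self.pulse_centers_by_class, self.pulse_amplitudes_by_class)):
            if len(cs) != len(am):
                raise ValueError(f"class {c}: centers and amplitudes differ in length")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class entries must be nonnegative")
        if self.series_length < 2:
            raise ValueError("series_length must be at least 2")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def default_config(**overrides) -> SimConfig:
    """The default 3-class imbalanced fixture (60/30/10 series of length 140)."""
    return SimConfig(**overrides)


def class_template(config: SimConfig, class_id: int) -> np.ndarray:
    """Noise-free pulse profile of one class on the fractional grid i/N."""
    if not 0 <= class_id < config.n_classes:
        raise ValueError(
            f"class_id {class_id} out of range for {config.n_classes} classes"
        )
    t = np.arange(config.series_length) / config.series_length
    x = np.zeros(config.series_length)
    centers = config.pulse_centers_by_class[class_id]
    amps = config.pulse_amplitudes_by_class[class_id]
    for c, a in zip(centers, amps):
        x += a * np.exp(-((t - c) ** 2) / (2.0 * config.pulse_width**2))
    return x


def generate_series(
    config: SimConfig, class_id: int, rng: np.random.Generator, id: str = ""
) -> TimeSeriesRecord:
    """One series: the class pulse template plus i.i.d. Gaussian noise."""
    x = class_template(config, class_id)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.size)
    return TimeSeriesRecord(values=x, label=class_id, id=id or f"c{class_id}")


def generate_dataset(config: SimConfig) -> LabeledDataset:
    """Full dataset with exactly ``n_per_class[c]`` records of each class.

    Per-record generators are spawned from ``config.seed`` so the dataset is
    byte-identical across calls and independent of generation order.
    """
    ss = np.random.SeedSequence(config.seed)
    total = int(sum(config.n_per_class))
    children = ss.spawn(max(total, 1))
    records = []
    idx = 0
    for c, n in enumerate(config.n_per_class):
        for j in range(n):
            rng = np.random.default_rng(children[idx])
            records.append(generate_series(config, c, rng, id=f"c{c}_{j}"))
            idx += 1
    return LabeledDataset(records=tuple(records))


def write_ucr(dataset: LabeledDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write label-then-values rows; ragged lengths are preserved."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in dataset.records:
            cells = [str(int(rec.label))] + [f"{v:.10g}" for v in rec.values]
            fh.write(delimiter.join(cells) + "\n")


def read_ucr(path: str | Path) -> LabeledDataset:
    """Read a UCR-style file: tab or comma delimited, integer or float labels.

    Raises ``ValueError`` naming the 1-based row index on any non-numeric cell.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split("\t") if "\t" in line else line.split(",")
            try:
                raw = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"non-numeric cell in row {i} of {path}") from exc
            if len(raw) < 3:
                raise ValueError(f"row {i} of {path} has fewer than 2 values")
            label = int(round(raw[0]))
            records.append(
                TimeSeriesRecord(values=np.array(raw[1:]), label=label, id=f"row{i}")
            )
    if not records:
        raise ValueError(f"{path} contains no series")
    return LabeledDataset(records=tuple(records))
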