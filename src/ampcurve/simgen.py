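"""Seeded synthetic amplification-curve generator for six morphology classes.

Curve morphologies (fluorescence vs. thermal cycle, normalized full scale = 1):

* ``class_A`` -- positive: sigmoid with a clear exponential phase and a
  plateau reached before the last cycle.
* ``class_B`` -- positive, late onset: sigmoid whose midpoint falls so late
  that the plateau is not reached within the run.
* ``class_C`` -- negative: flat baseline.
* ``class_D`` -- abnormal: baseline with a step jump in the last few cycles.
* ``class_E`` -- abnormal "hook": rises like a sigmoid, then declines.
* ``class_F`` -- abnormal: linear upward drift over the whole run.

All classes carry additive Gaussian noise (clipped at zero fluorescence).
Per-curve random substreams are derived from the root seed by counter, so
changing the per-class count never reshuffles earlier curves.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "CurveClass",
    "Group",
    "FluorescenceCurve",
    "SimConfig",
    "LabeledDataset",
    "simulate_curve",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "DatasetParseError",
]


class Group(str, enum.Enum):
    """Three-way verdict group of a curve class."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    ABNORMAL = "abnormal"


class CurveClass(str, enum.Enum):
    """Six-way curve morphology label."""

    A = "class_A"
    B = "class_B"
    C = "class_C"
    D = "class_D"
    E = "class_E"
    F = "class_F"

    @property
    def group(self) -> Group:
        return _GROUPS[self]

    @classmethod
    def from_label(cls, label: str) -> "CurveClass":
        try:
            return cls(label)
        except ValueError:
            raise InvalidClassError(f"unknown curve class label: {label!r}") from None


_GROUPS = {
    CurveClass.A: Group.POSITIVE,
    CurveClass.B: Group.POSITIVE,
    CurveClass.C: Group.NEGATIVE,
    CurveClass.D: Group.ABNORMAL,
    CurveClass.E: Group.ABNORMAL,
    CurveClass.F: Group.ABNORMAL,
}


class InvalidClassError(ValueError):
    """Raised for a label outside the six known curve classes."""


class DatasetParseError(ValueError):
    """Raised when a serialized dataset file is malformed."""


@dataclass(frozen=True)
class FluorescenceCurve:
    """One well's amplification trace: fluorescence read once per cycle.

    ``cycles`` are 1-based consecutive integers; ``rfu`` holds the matching
    relative-fluorescence values.
    """

    cycles: np.ndarray
    rfu: np.ndarray
    well_id: str | None = None

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=int)
        rfu = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "rfu", rfu)
        if cycles.ndim != 1 or rfu.ndim != 1:
            raise ValueError("cycles and rfu must be one-dimensional")
        if len(cycles) != len(rfu):
            raise ValueError("cycles and rfu must have equal length")
        if len(cycles) < 10:
            raise ValueError("a curve needs at least 10 cycles")
        if not np.array_equal(cycles, np.arange(1, len(cycles) + 1)):
            raise ValueError("cycles must be consecutive integers starting at 1")
        if not np.all(np.isfinite(rfu)):
            raise ValueError("rfu values must be finite")

    def __len__(self) -> int:
        return len(self.cycles)

    @classmethod
    def from_rfu(cls, rfu: Sequence[float], well_id: str | None = None) -> "FluorescenceCurve":
        rfu = np.asarray(rfu, dtype=float)
        return cls(cycles=np.arange(1, len(rfu) + 1), rfu=rfu, well_id=well_id)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Parameter ranges are expressed in normalized fluorescence units where the
    full scale is 1.0; uniform draws within each range.
    """

    n_cycles: int = 40
    per_class_n: int = 100
    noise_sd: float = 0.002
    seed: int = 0
    baseline_range: tuple[float, float] = (0.049, 0.051)
    amplitude_range: tuple[float, float] = (0.845, 0.855)
    # class_A: full sigmoid, plateau reached before the end of the run
    a_midpoint_range: tuple[float, float] = (24.0, 30.0)
    a_slope_range: tuple[float, float] = (1.2, 1.6)
    a_asym_range: tuple[float, float] = (0.99, 1.01)
    # class_B: late-onset sigmoid, midpoint past cycle 30
    b_midpoint_range: tuple[float, float] = (31.0, 38.0)
    b_slope_range: tuple[float, float] = (1.2, 1.6)
    b_asym_range: tuple[float, float] = (0.99, 1.01)
    # class_D: end-of-run jump over the last cycles, well above noise
    d_jump_range: tuple[float, float] = (0.06, 0.10)
    d_jump_cycles: tuple[int, int] = (1, 2)
    # class_E: hook -- sigmoidal rise then linear decline past the peak
    e_midpoint_range: tuple[float, float] = (11.0, 14.0)
    e_slope_range: tuple[float, float] = (1.0, 1.2)
    e_decay_range: tuple[float, float] = (0.015, 0.017)
    # class_F: linear drift across the whole run (fraction of full scale/cycle)
    f_slope_range: tuple[float, float] = (0.015, 0.017)

    def __post_init__(self) -> None:
        if self.n_cycles < 10:
            raise ValueError("n_cycles must be >= 10")
        if self.per_class_n < 1:
            raise ValueError("per_class_n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LabeledDataset:
    """A labeled corpus of simulated curves."""

    samples: tuple[tuple[FluorescenceCurve, CurveClass], ...]
    seed: int | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for _, label in self.samples:
            counts[label.value] = counts.get(label.value, 0) + 1
        object.__setattr__(self, "class_counts", counts)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[tuple[FluorescenceCurve, CurveClass]]:
        return iter(self.samples)

    @property
    def n_cycles(self) -> int:
        return len(self.samples[0][0]) if self.samples else 0

    def feature_matrix(self) -> np.ndarray:
        """(n_samples, n_cycles) matrix of raw per-cycle fluorescence."""
        return np.vstack([c.rfu for c, _ in self.samples])

    def labels(self) -> np.ndarray:
        return np.array([lab.value for _, lab in self.samples])

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            samples=tuple(self.samples[i] for i in indices), seed=self.seed
        )


def _sigmoid(x: np.ndarray, x0: float, k: float, s: float = 1.0) -> np.ndarray:
    return (1.0 + np.exp(-(x - x0) / k)) ** (-s)


def _curve_rng(config: SimConfig, label: CurveClass, index: int) -> np.random.Generator:
    # counter-keyed substream: independent of per_class_n and draw order
    class_idx = list(CurveClass).index(label)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(class_idx, index))
    )


def simulate_curve(
    label: CurveClass,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    index: int = 0,
    well_id: str | None = None,
) -> FluorescenceCurve:
    """Generate one curve of the given morphology class.

    Deterministic given ``(label, config, rng)``; when ``rng`` is omitted the
    counter-derived substream for ``(label, index)`` under ``config.seed`` is
    used.
    """
    if config is None:
        config = SimConfig()
    if not isinstance(label, CurveClass):
        label = CurveClass.from_label(str(label))
    if rng is None:
        rng = _curve_rng(config, label, index)

    x = np.arange(1, config.n_cycles + 1, dtype=float)
    baseline = rng.uniform(*config.baseline_range)
    amplitude = rng.uniform(*config.amplitude_range)

    if label is CurveClass.A:
        x0 = rng.uniform(*config.a_midpoint_range)
        k = rng.uniform(*config.a_slope_range)
        s = rng.uniform(*config.a_asym_range)
        clean = baseline + amplitude * _sigmoid(x, x0, k, s)
    elif label is CurveClass.B:
        x0 = rng.uniform(*config.b_midpoint_range)
        k = rng.uniform(*config.b_slope_range)
        s = rng.uniform(*config.b_asym_range)
        clean = baseline + amplitude * _sigmoid(x, x0, k, s)
    elif label is CurveClass.C:
        clean = np.full_like(x, baseline)
    elif label is CurveClass.D:
        clean = np.full_like(x, baseline)
        jump = rng.uniform(*config.d_jump_range)
        width = rng.integers(config.d_jump_cycles[0], config.d_jump_cycles[1] + 1)
        clean[config.n_cycles - width :] += jump
    elif label is CurveClass.E:
        x0 = rng.uniform(*config.e_midpoint_range)
        k = rng.uniform(*config.e_slope_range)
        decay = rng.uniform(*config.e_decay_range)
        rise = _sigmoid(x, x0, k)
        # linear decay engages past the sigmoid's effective peak, giving a
        # single interior maximum (rise-then-decline hook)
        peak = x0 + 4.0 * k
        fall = 1.0 - decay * np.maximum(x - peak, 0.0)
        clean = baseline + amplitude * rise * fall
    elif label is CurveClass.F:
        slope = rng.uniform(*config.f_slope_range)
        clean = baseline + slope * x
    else:  # pragma: no cover - enum is exhaustive
        raise InvalidClassError(f"unknown curve class: {label!r}")

    if config.noise_sd > 0:
        clean = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
    rfu = np.clip(clean, 0.0, None)
    return FluorescenceCurve(cycles=np.arange(1, config.n_cycles + 1), rfu=rfu, well_id=well_id)


def simulate_dataset(config: SimConfig | None = None) -> LabeledDataset:
    """Generate the full labeled corpus: ``per_class_n`` curves per class,
    shuffled with the config seed. Identical configs yield identical datasets.
    """
    if config is None:
        config = SimConfig()
    samples: list[tuple[FluorescenceCurve, CurveClass]] = []
    for label in CurveClass:
        for i in range(config.per_class_n):
            curve = simulate_curve(
                label, config, index=i, well_id=f"{label.value}_{i:03d}"
            )
            samples.append((curve, label))
    order_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999,))
    )
    order = order_rng.permutation(len(samples))
    return LabeledDataset(
        samples=tuple(samples[i] for i in order), seed=config.seed
    )


def write_dataset(ds: LabeledDataset, path) -> None:
    """Serialize to CSV: header ``label,c1..cN``, one row per sample."""
    n = ds.n_cycles
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label"] + [f"c{i}" for i in range(1, n + 1)])
        for curve, label in ds.samples:
            writer.writerow([label.value] + [repr(float(v)) for v in curve.rfu])


def read_dataset(path) -> LabeledDataset:
    """Parse a dataset CSV written by :func:`write_dataset`.

    Raises :class:`DatasetParseError` naming the offending row on malformed
    input.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetParseError(f"{path}: empty file") from None
        if not header or header[0] != "label":
            raise DatasetParseError(f"{path}: header must start with 'label'")
        width = len(header)
        if width < 11:
            raise DatasetParseError(f"{path}: header declares fewer than 10 cycles")
        samples: list[tuple[FluorescenceCurve, CurveClass]] = []
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise DatasetParseError(
                    f"{path}: row {row_no} has {len(row)} fields, expected {width}"
                )
            try:
                label = CurveClass.from_label(row[0])
            except InvalidClassError as exc:
                raise DatasetParseError(f"{path}: row {row_no}: {exc}") from None
            try:
                rfu = np.array([float(v) for v in row[1:]])
            except ValueError:
                raise DatasetParseError(
                    f"{path}: row {row_no}: non-numeric fluorescence value"
                ) from None
            samples.append((FluorescenceCurve.from_rfu(rfu), label))
        if not samples:
            raise DatasetParseError(f"{path}: no sample rows")
    return LabeledDataset(samples=tuple(samples))


def config_from_mapping(mapping: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (e.g. parsed YAML)."""
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return replace(SimConfig(), **kwargs)
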