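"""Core dataset types and spectral-table I/O.

A :class:`SpectralDataset` is the container every pipeline stage consumes:
an ``N x P`` matrix of dielectric values (relative permittivity, dimensionless,
or conductivity in S/m) measured on a common frequency grid, with one binary
class label per sample (positive = metastatic).

The on-disk exchange format is a plain CSV with header
``sample_id,label,<f1>MHz,<f2>MHz,...`` — one row per sample, UTF-8,
``.`` decimal separator.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParamKind",
    "ClassLabel",
    "FrequencyGrid",
    "SpectralDataset",
    "FeatureVectorSpec",
    "ValidationError",
    "SpectralParseError",
    "FrequencyLookupError",
    "make_uniform_grid",
    "read_spectral_csv",
    "write_spectral_csv",
    "select_features",
]

#: Absolute tolerance (MHz) when matching a requested frequency to a grid
#: column; printed decimals in CSV headers round-trip well within this.
FREQ_MATCH_TOL_MHZ = 1e-6


class SapnnError(Exception):
    """Base class for package errors."""


class ValidationError(SapnnError, ValueError):
    """Invalid argument or inconsistent object state."""


class SpectralParseError(SapnnError, ValueError):
    """Malformed spectral CSV; message carries row/column coordinates."""


class FrequencyLookupError(SapnnError, KeyError):
    """Requested frequency absent from the dataset grid."""


class ParamKind(str, enum.Enum):
    PERMITTIVITY = "permittivity"
    CONDUCTIVITY = "conductivity"


class ClassLabel(enum.IntEnum):
    """Binary class; POSITIVE is the metastatic/tumor class."""

    NEGATIVE = 0
    POSITIVE = 1


@dataclass(frozen=True)
class FrequencyGrid:
    """Ascending frequency axis in MHz.

    ``step_mhz`` is ``None`` for a non-uniform grid (e.g. parsed from an
    arbitrary CSV header).
    """

    start_mhz: float
    stop_mhz: float
    step_mhz: float | None
    points: np.ndarray  # 1-D float64, strictly increasing

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size == 0:
            raise ValidationError("points: must be a non-empty 1-D array")
        if pts.size > 1 and not np.all(np.diff(pts) > 0):
            raise ValidationError("points: must be strictly increasing")
        if abs(pts[0] - self.start_mhz) > FREQ_MATCH_TOL_MHZ:
            raise ValidationError("start_mhz: does not match first grid point")
        if abs(pts[-1] - self.stop_mhz) > FREQ_MATCH_TOL_MHZ:
            raise ValidationError("stop_mhz: does not match last grid point")

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    def __len__(self) -> int:
        return self.n_points

    def index_of(self, frequency_mhz: float) -> int:
        """Column index of ``frequency_mhz``, matched within 1e-6 MHz."""
        hits = np.nonzero(np.abs(self.points - frequency_mhz) <= FREQ_MATCH_TOL_MHZ)[0]
        if hits.size == 0:
            raise FrequencyLookupError(
                f"frequency {frequency_mhz} MHz not on grid "
                f"[{self.start_mhz}..{self.stop_mhz}] MHz"
            )
        return int(hits[0])


def make_uniform_grid(start_mhz: float, stop_mhz: float, step_mhz: float) -> FrequencyGrid:
    """Inclusive uniform grid from ``start_mhz`` to ``stop_mhz``.

    The span must be an integer multiple of ``step_mhz`` (tolerance 1e-9
    relative to the step), so both endpoints land exactly on the grid. The
    canonical measurement axis, 50 MHz to 4 GHz at 1 MHz, has 3951 points.
    """
    if not (0 < start_mhz < stop_mhz):
        raise ValidationError(
            f"start_mhz/stop_mhz: need 0 < start < stop, got ({start_mhz}, {stop_mhz})"
        )
    if step_mhz <= 0:
        raise ValidationError(f"step_mhz: must be positive, got {step_mhz}")
    span = stop_mhz - start_mhz
    n_steps = span / step_mhz
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
        raise ValidationError(
            f"step_mhz: span {span} MHz is not an integer multiple of step {step_mhz} MHz"
        )
    n = int(round(n_steps)) + 1
    points = start_mhz + step_mhz * np.arange(n, dtype=float)
    points[-1] = stop_mhz  # kill accumulated rounding at the far end
    return FrequencyGrid(start_mhz=float(start_mhz), stop_mhz=float(stop_mhz),
                         step_mhz=float(step_mhz), points=points)


@dataclass
class SpectralDataset:
    """Labeled spectral feature table.

    ``features[i, j]`` is the dielectric value of sample ``i`` at
    ``grid.points[j]``; ``labels[i]`` is a :class:`ClassLabel`.
    """

    features: np.ndarray
    grid: FrequencyGrid
    param_kind: ParamKind
    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.param_kind = ParamKind(self.param_kind)
        if self.features.ndim != 2:
            raise ValidationError("features: must be a 2-D matrix")
        n, p = self.features.shape
        if n < 1 or p < 1:
            raise ValidationError("features: need N >= 1 and P >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features: contains non-finite values")
        if p != self.grid.n_points:
            raise ValidationError(
                f"features: {p} columns but grid has {self.grid.n_points} points"
            )
        if self.labels.shape != (n,):
            raise ValidationError("labels: length must equal number of samples")
        if not np.all(np.isin(self.labels, (ClassLabel.NEGATIVE, ClassLabel.POSITIVE))):
            raise ValidationError("labels: values must be ClassLabel members")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids: length must equal number of samples")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids: duplicates present")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[ClassLabel, int]:
        return {c: int(np.sum(self.labels == c)) for c in ClassLabel}


@dataclass
class FeatureVectorSpec:
    """Ordered frequency subset used as the classifier input vector."""

    param_kind: ParamKind
    frequencies_mhz: list[float]
    column_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.param_kind = ParamKind(self.param_kind)
        if len(self.frequencies_mhz) == 0:
            raise ValidationError("frequencies_mhz: must be non-empty")

    def resolve(self, grid: FrequencyGrid) -> list[int]:
        """Map frequencies to grid columns; raises if any is off-grid."""
        missing: list[float] = []
        idx: list[int] = []
        for f in self.frequencies_mhz:
            try:
                idx.append(grid.index_of(f))
            except FrequencyLookupError:
                missing.append(f)
        if missing:
            raise FrequencyLookupError(
                f"frequencies not on grid (MHz): {missing}"
            )
        if len(set(idx)) != len(idx):
            raise ValidationError("frequencies_mhz: resolve to duplicate columns")
        self.column_indices = idx
        return idx

    def to_dict(self) -> dict:
        return {
            "param_kind": self.param_kind.value,
            "frequencies_mhz": [float(f) for f in self.frequencies_mhz],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVectorSpec":
        return cls(param_kind=ParamKind(d["param_kind"]),
                   frequencies_mhz=[float(f) for f in d["frequencies_mhz"]])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureVectorSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_FREQ_COL_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*MHz\s*$")


def read_spectral_csv(
    path: str | Path,
    *,
    positive_label: str = "metastatic",
    param_kind: ParamKind | str = ParamKind.CONDUCTIVITY,
) -> SpectralDataset:
    """Read a spectral CSV into a :class:`SpectralDataset`.

    Header must be ``sample_id,label`` followed by one ``<value>MHz`` column
    per frequency; columns may appear in any order and are sorted ascending.
    ``positive_label`` names the class mapped to :data:`ClassLabel.POSITIVE`;
    exactly one other label value may occur and maps to NEGATIVE.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw_header = fh.readline().rstrip("\r\n").split(",")
    if len(raw_header) != len(set(raw_header)):
        dup = next(c for i, c in enumerate(raw_header) if c in raw_header[:i])
        raise SpectralParseError(f"{path}: duplicate frequency column '{dup}'")
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "label":
        raise SpectralParseError(
            f"{path}: header must start with 'sample_id,label', got {cols[:2]}"
        )
    freqs: list[float] = []
    for j, c in enumerate(cols[2:], start=3):
        m = _FREQ_COL_RE.match(c)
        if not m:
            raise SpectralParseError(f"{path}: column {j} ('{c}') is not a '<value>MHz' header")
        freqs.append(float(m.group(1)))
    freqs_arr = np.asarray(freqs)
    order = np.argsort(freqs_arr, kind="stable")
    sorted_freqs = freqs_arr[order]
    if np.any(np.diff(sorted_freqs) <= FREQ_MATCH_TOL_MHZ):
        dup = sorted_freqs[np.nonzero(np.diff(sorted_freqs) <= FREQ_MATCH_TOL_MHZ)[0][0]]
        raise SpectralParseError(f"{path}: duplicate frequency column near {dup} MHz")

    ids = df["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup_id = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise SpectralParseError(f"{path}: duplicate sample_id '{dup_id}'")

    raw_labels = df["label"].tolist()
    others = sorted(set(raw_labels) - {positive_label})
    if len(others) > 1:
        raise SpectralParseError(
            f"{path}: unknown label values {others} (positive class is '{positive_label}')"
        )
    labels = np.array(
        [ClassLabel.POSITIVE if v == positive_label else ClassLabel.NEGATIVE for v in raw_labels],
        dtype=np.int64,
    )

    values = np.empty((len(df), len(freqs)), dtype=float)
    for k, c in enumerate(cols[2:]):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(~np.isfinite(col.to_numpy(dtype=float)))[0]
        if bad.size:
            raise SpectralParseError(
                f"{path}: non-numeric cell at row {int(bad[0]) + 2}, column '{c}'"
            )
        values[:, k] = col.to_numpy(dtype=float)
    values = values[:, order]

    step = None
    if sorted_freqs.size > 1:
        diffs = np.diff(sorted_freqs)
        if np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
            step = float(diffs[0])
    grid = FrequencyGrid(start_mhz=float(sorted_freqs[0]), stop_mhz=float(sorted_freqs[-1]),
                         step_mhz=step, points=sorted_freqs)
    return SpectralDataset(features=values, grid=grid, param_kind=ParamKind(param_kind),
                           labels=labels, sample_ids=[str(i) for i in ids])


def write_spectral_csv(
    ds: SpectralDataset,
    path: str | Path,
    *,
    positive_name: str = "metastatic",
    negative_name: str = "non-metastatic",
) -> None:
    """Write the standard spectral CSV (inverse of :func:`read_spectral_csv`)."""
    header = ["sample_id", "label"] + [_format_freq(f) + "MHz" for f in ds.grid.points]
    names = np.where(ds.labels == ClassLabel.POSITIVE, positive_name, negative_name)
    out = pd.DataFrame(ds.features, columns=header[2:])
    out.insert(0, "label", names)
    out.insert(0, "sample_id", ds.sample_ids)
    out.to_csv(path, index=False, float_format="%.10g")


def _format_freq(f: float) -> str:
    return f"{f:.6f}".rstrip("0").rstrip(".")


def select_features(
    ds: SpectralDataset, spec: FeatureVectorSpec, *, zscore: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Project the dataset onto the spec's frequencies, in spec order.

    Returns ``(X, labels)`` where ``X`` is ``N x K`` with one column per
    spec frequency; labels pass through unchanged. Values are used unscaled
    by default; ``zscore=True`` standardizes each selected column (constant
    columns become zero).
    """
    if ParamKind(spec.param_kind) != ds.param_kind:
        raise ValidationError(
            f"param_kind mismatch: spec={spec.param_kind.value}, dataset={ds.param_kind.value}"
        )
    idx = spec.resolve(ds.grid)
    X = ds.features[:, idx]
    if zscore:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X, ds.labels.copy()
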