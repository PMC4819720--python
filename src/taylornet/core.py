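"""Core containers for regional time series and weighted adjacency matrices.

Everything downstream operates on two objects: :class:`RegionalTimeSeries`,
a regions x samples array with a sampling rate, and
:class:`ConnectivityMatrix`, a symmetric zero-diagonal weighted adjacency
matrix for one (metric, frequency band) pair.  A :class:`MatrixStack` is an
ordered collection of connectivity matrices sharing one region set; it is
the multivariate input of the Taylor-expansion model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "RegionalTimeSeries",
    "VoxelGroup",
    "ConnectivityMatrix",
    "MatrixStack",
    "ValidationError",
    "DegenerateSignalWarning",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class DegenerateSignalWarning(UserWarning):
    """Emitted when a degenerate (constant or collinear) channel is handled."""


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValidationError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} ({self.low}-{self.high} Hz)"


#: The five canonical electrophysiological bands used throughout.
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 1.0, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha", 8.0, 13.0),
    FrequencyBand("beta", 13.0, 30.0),
    FrequencyBand("gamma", 30.0, 48.0),
)


def band_by_name(name: str) -> FrequencyBand:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in CANONICAL_BANDS]}")


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"R{str(i + 1).zfill(width)}" for i in range(n)]


@dataclass
class RegionalTimeSeries:
    """Regional time courses: a regions x samples real array at a fixed rate.

    Parameters
    ----------
    data : ndarray, shape (P, T)
        One row per region.
    sampling_rate : float
        Samples per second (Hz).
    region_labels : sequence of str, optional
        Defaults to ``R1..RP``.
    band : FrequencyBand, optional
        Set once the series has been band-pass filtered.
    modality : str
        ``"electrophysiological"`` or ``"haemodynamic"``.
    """

    data: np.ndarray
    sampling_rate: float
    region_labels: list[str] = field(default_factory=list)
    band: FrequencyBand | None = None
    modality: str = "electrophysiological"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be 2-D (regions x samples)")
        p, t = self.data.shape
        if p < 2 or t < 2:
            raise ValidationError(f"need >= 2 regions and >= 2 samples, got {p}x{t}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time-series data contains NaN/inf")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not self.region_labels:
            self.region_labels = _default_labels(p)
        if len(self.region_labels) != p:
            raise ValidationError("region_labels length must equal number of rows")
        if self.modality not in ("electrophysiological", "haemodynamic"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.band is not None and self.sampling_rate <= 2 * self.band.high:
            raise ValidationError(
                f"sampling rate {self.sampling_rate} Hz violates Nyquist for "
                f"band {self.band}"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray, band: FrequencyBand | None = None) -> "RegionalTimeSeries":
        return RegionalTimeSeries(
            data=np.asarray(data, dtype=float),
            sampling_rate=self.sampling_rate,
            region_labels=list(self.region_labels),
            band=band if band is not None else self.band,
            modality=self.modality,
        )


@dataclass
class VoxelGroup:
    """Voxel signals within one region plus distances to its centre of mass."""

    voxel_data: np.ndarray
    distances_mm: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_data = np.atleast_2d(np.asarray(self.voxel_data, dtype=float))
        self.distances_mm = np.atleast_1d(np.asarray(self.distances_mm, dtype=float))
        if self.voxel_data.shape[0] != self.distances_mm.shape[0]:
            raise ValidationError("one distance per voxel required")
        if self.voxel_data.shape[0] < 1:
            raise ValidationError("at least one voxel required")
        if np.any(self.distances_mm < 0):
            raise ValidationError("distances must be non-negative")


_METRIC_RANGES = {
    "PLI": (0.0, 1.0),
    "AEC": (-1.0, 1.0),
    "Pearson": (-1.0, 1.0),
}

SYMMETRY_TOL = 1e-12


@dataclass
class ConnectivityMatrix:
    """A P x P symmetric, zero-diagonal weighted adjacency matrix.

    Entries are connectivity strengths between region pairs for one metric
    and (optionally) one frequency band.  The zero diagonal guarantees
    ``trace(W) = 0`` and hence that the eigenvalues sum to zero, which is
    what makes the Taylor expansion about zero well behaved.
    """

    weights: np.ndarray
    metric: str = "generic"
    band: FrequencyBand | None = None
    region_labels: list[str] = field(default_factory=list)
    #: range-check entries against the metric's domain; surrogate matrices
    #: (spectrum preserved, entries unconstrained) set this to False
    check_range: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValidationError("weights contain NaN/inf")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"matrix asymmetric beyond tolerance: max |W-W.T| = {asym:g}")
        w = 0.5 * (w + w.T)  # absorb float round-off
        if np.max(np.abs(np.diag(w))) > 0:
            raise ValidationError("diagonal must be exactly zero")
        if self.check_range and self.metric in _METRIC_RANGES:
            lo, hi = _METRIC_RANGES[self.metric]
            if w.min() < lo - 1e-12 or w.max() > hi + 1e-12:
                raise ValidationError(
                    f"{self.metric} entries must lie in [{lo}, {hi}]; "
                    f"observed range [{w.min():g}, {w.max():g}]"
                )
        self.weights = w
        if not self.region_labels:
            self.region_labels = _default_labels(w.shape[0])
        if len(self.region_labels) != w.shape[0]:
            raise ValidationError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def key(self) -> tuple[str, str | None]:
        """(metric, band name) identifier used inside a stack."""
        return (self.metric, self.band.name if self.band else None)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues (symmetric matrix), ascending."""
        return np.linalg.eigvalsh(self.weights)

    def upper_values(self) -> np.ndarray:
        """The E = P(P-1)/2 strictly upper-triangular entries."""
        iu = np.triu_indices(self.n_regions, 1)
        return self.weights[iu]


def check_same_regions(mats: Iterable[ConnectivityMatrix]) -> list[str]:
    labels: list[str] | None = None
    for m in mats:
        if labels is None:
            labels = m.region_labels
        elif m.region_labels != labels:
            raise ValidationError("matrices do not share region labels/order")
    if labels is None:
        raise ValidationError("empty matrix collection")
    return labels


@dataclass
class MatrixStack:
    """Ordered collection W = (W_1, ..., W_D) over one region set."""

    matrices: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValidationError("stack needs at least one matrix")
        check_same_regions(self.matrices)
        keys = [m.key for m in self.matrices]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            warnings.warn(f"duplicate (metric, band) keys in stack: {dupes}")

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, i: int) -> ConnectivityMatrix:
        return self.matrices[i]

    @property
    def D(self) -> int:
        return len(self.matrices)

    @property
    def n_regions(self) -> int:
        return self.matrices[0].n_regions

    @property
    def region_labels(self) -> list[str]:
        return self.matrices[0].region_labels

    @property
    def keys(self) -> list[tuple[str, str | None]]:
        return [m.key for m in self.matrices]

    @property
    def metrics(self) -> list[str]:
        seen: list[str] = []
        for m in self.matrices:
            if m.metric not in seen:
                seen.append(m.metric)
        return seen

    @property
    def bands(self) -> list[FrequencyBand]:
        seen: list[FrequencyBand] = []
        for m in self.matrices:
            if m.band is not None and m.band not in seen:
                seen.append(m.band)
        return seen

    def get(self, metric: str, band_name: str | None) -> ConnectivityMatrix:
        for m in self.matrices:
            if m.key == (metric, band_name):
                return m
        raise KeyError(f"no matrix with key {(metric, band_name)} in stack")

    def subset(
        self,
        metrics: Sequence[str] | None = None,
        band_names: Sequence[str] | None = None,
    ) -> "MatrixStack":
        """Stack restricted to the given metrics/bands (original order kept)."""
        picked = [
            m
            for m in self.matrices
            if (metrics is None or m.metric in metrics)
            and (band_names is None or (m.band is not None and m.band.name in band_names))
        ]
        if not picked:
            raise ValidationError(
                f"subset(metrics={metrics}, bands={band_names}) selected no matrices"
            )
        return MatrixStack(picked)

    def as_array(self) -> np.ndarray:
        """(D, P, P) array view of the stacked weights."""
        return np.stack([m.weights for m in self.matrices])
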