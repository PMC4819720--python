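"""Synthetic inputs: adjacency stacks, planted targets, coupled oscillators.

No public recordings accompany the mapping problem this package solves,
so validation rests on synthetic data with known ground truth at three
levels:

* :func:`gen_stack` — stacks of symmetric zero-diagonal adjacency
  matrices with entries in the metric's range, optionally with modular
  (block) community structure;
* :func:`plant_target` — a target matrix built from the second-order
  expansion forward model with known coefficients plus symmetric noise,
  so the fitting machinery can be checked by exact recovery;
* :func:`gen_coupled_timeseries` — multi-band oscillatory time series
  with planted constant phase lags (detected by PLI) and planted
  envelope correlations (detected by AEC) on chosen region pairs.

One top-level seed expands into independent per-component child streams
through ``numpy.random.SeedSequence(seed).spawn``, in the fixed order the
docstrings state, so each sub-generator is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

from .core import (
    CANONICAL_BANDS,
    ConnectivityMatrix,
    FrequencyBand,
    MatrixStack,
    RegionalTimeSeries,
    ValidationError,
)
from .taylor import (
    ModelSpec,
    TaylorNetworkModel,
    build_terms,
    count_coefficients,
)

__all__ = [
    "SyntheticSpec",
    "CouplingSpec",
    "gen_stack",
    "plant_target",
    "gen_coupled_timeseries",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic stack-and-target pair.

    Defaults mirror the study conditions the model was designed for:
    78 cortical regions and a ten-matrix stack (five frequency bands by
    two coupling metrics).  ``noise_sd = 0.05`` is a realistic
    measurement-noise scale for group-averaged correlation-valued
    connectivity entries.  Coefficients left at ``None`` are drawn once,
    deterministically from ``seed``, on first use.
    """

    P: int = 78
    D: int = 10
    planted_a: np.ndarray | None = None
    planted_b: np.ndarray | None = None
    planted_c: float | None = None
    noise_sd: float = 0.05
    structure: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 3:
            raise ValidationError("P must be >= 3")
        if self.D < 1:
            raise ValidationError("D must be >= 1")
        if self.D > 10:
            raise ValidationError("at most 10 matrices (5 bands x 2 metrics)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.structure not in ("random", "modular"):
            raise ValidationError("structure must be 'random' or 'modular'")
        if self.planted_a is not None:
            self.planted_a = np.asarray(self.planted_a, dtype=float)
            if self.planted_a.shape != (self.D,):
                raise ValidationError(f"planted_a must have shape ({self.D},)")
        if self.planted_b is not None:
            self.planted_b = np.asarray(self.planted_b, dtype=float)
            if self.planted_b.shape != (self.D, self.D):
                raise ValidationError(f"planted_b must be {self.D}x{self.D}")
            if not np.allclose(self.planted_b, self.planted_b.T):
                raise ValidationError("planted_b must be symmetric")

    def _seeds(self) -> dict[str, np.random.Generator]:
        """Child streams, spawned in fixed order: stack, coefficients, noise."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "stack": np.random.default_rng(children[0]),
            "coefficients": np.random.default_rng(children[1]),
            "noise": np.random.default_rng(children[2]),
        }

    def coefficients(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Planted (a, b, c), drawing unspecified ones from the seed."""
        rng = self._seeds()["coefficients"]
        a = self.planted_a
        if a is None:
            a = rng.uniform(-1.0, 1.0, size=self.D)
        b = self.planted_b
        if b is None:
            raw = rng.uniform(-0.5, 0.5, size=(self.D, self.D))
            b = 0.5 * (raw + raw.T)
        c = self.planted_c
        if c is None:
            c = float(rng.uniform(-0.2, 0.2))
        return a, b, c

    @property
    def fit_spec(self) -> ModelSpec:
        """The model that matches the planted structure."""
        metrics = _stack_keys(self.D)[1]
        variant = "full" if len(metrics) > 1 else "nonlinear_cross"
        return ModelSpec(variant, metrics=tuple(metrics))


def _stack_keys(d: int) -> tuple[list[tuple[str, FrequencyBand]], list[str]]:
    """(metric, band) labelling for a D-matrix stack: AEC bands first."""
    keys: list[tuple[str, FrequencyBand]] = []
    for metric in ("AEC", "PLI"):
        for band in CANONICAL_BANDS:
            keys.append((metric, band))
    keys = keys[:d]
    metrics = []
    for m, _ in keys:
        if m not in metrics:
            metrics.append(m)
    return keys, metrics


def _random_symmetric(
    p: int, rng: np.random.Generator, structure: str, nonnegative: bool
) -> np.ndarray:
    if structure == "modular":
        half = p // 2
        base = np.full((p, p), 0.10)
        base[:half, :half] = 0.35
        base[half:, half:] = 0.35
        w = base + rng.normal(0.0, 0.10, size=(p, p))
    else:
        w = rng.normal(0.0, 0.20, size=(p, p))
    w = 0.5 * (w + w.T)
    if nonnegative:
        w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    return np.clip(w, -1.0 if not nonnegative else 0.0, 1.0)


def gen_stack(spec: SyntheticSpec) -> MatrixStack:
    """A D-matrix stack of valid connectivity matrices.

    Matrices are labelled (AEC, delta..gamma) then (PLI, delta..gamma);
    PLI-labelled matrices are non-negative as the metric demands.
    ``modular`` plants two equal blocks with elevated within-block
    weights.  Deterministic given ``spec.seed``.
    """
    rng = spec._seeds()["stack"]
    keys, _ = _stack_keys(spec.D)
    mats = []
    for metric, band in keys:
        w = _random_symmetric(spec.P, rng, spec.structure, nonnegative=(metric == "PLI"))
        mats.append(ConnectivityMatrix(w, metric=metric, band=band))
    return MatrixStack(mats)


def plant_target(stack: MatrixStack, spec: SyntheticSpec) -> ConnectivityMatrix:
    """Target matrix from the expansion forward model plus symmetric noise.

    V = sum a_m W_m + sum_{m<=n} b_mn sym(W_m W_n) + c (uu^T - I) + noise,
    with the same symmetrized-product regressor convention the fitting
    code uses, so a noiseless target is recovered exactly.  Entries may
    leave [-1, 1]; they are deliberately not clipped (clipping would bias
    recovery) — shrink the coefficients for correlation-like targets.
    """
    if stack.D != spec.D:
        raise ValidationError(f"stack has D={stack.D} but spec.D={spec.D}")
    a, b, c = spec.coefficients()
    terms = build_terms(stack, spec.fit_spec)
    theta = np.concatenate(
        [a, [b[m, n] for (m, n) in terms.quad_pairs], [c]]
    )
    p = stack.n_regions
    v = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    v[iu] = terms.design @ theta
    if spec.noise_sd > 0:
        rng = spec._seeds()["noise"]
        v[iu] += rng.normal(0.0, spec.noise_sd, size=iu[0].size)
    v = v + v.T
    return ConnectivityMatrix(
        v, metric="generic", region_labels=stack.region_labels, check_range=False
    )


@dataclass
class CouplingSpec:
    """Planted coupling within one frequency band.

    ``phase_lag_edges`` are (i, j, lag) triples: region j's band carrier
    is region i's carrier delayed by a constant phase, which the PLI
    detects.  ``envelope_corr_edges`` are (i, j, rho) triples: the two
    regions keep independent carriers but share a slow log-normal
    amplitude modulator mixed to envelope correlation ~rho, which the AEC
    detects while the PLI stays at its null level.
    """

    band: FrequencyBand
    phase_lag_edges: list[tuple[int, int, float]] = field(default_factory=list)
    envelope_corr_edges: list[tuple[int, int, float]] = field(default_factory=list)
    duration_s: float = 300.0
    sampling_rate: float = 600.0

    def __post_init__(self) -> None:
        for i, j, lag in self.phase_lag_edges:
            if i == j:
                raise ValidationError("phase-lag edge must join two distinct regions")
            if not (-np.pi < lag < np.pi):
                raise ValidationError("lag must lie in (-pi, pi)")
        for i, j, rho in self.envelope_corr_edges:
            if i == j:
                raise ValidationError("envelope edge must join two distinct regions")
            if not (-1 < rho < 1):
                raise ValidationError("target correlation must lie in (-1, 1)")
        if self.sampling_rate <= 2 * self.band.high:
            raise ValidationError("sampling rate violates Nyquist for the band")
        touched: set[int] = set()
        for i, j, _ in self.phase_lag_edges + self.envelope_corr_edges:
            for r in (i, j):
                if r in touched:
                    raise ValidationError(
                        f"region {r} appears in more than one planted edge "
                        f"in band {self.band.name}"
                    )
                touched.add(r)


def _bandlimited_noise(
    band: FrequencyBand, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    nyq = fs / 2.0
    b, a = butter(4, [band.low / nyq, band.high / nyq], btype="bandpass")
    x = filtfilt(b, a, rng.standard_normal(n))
    return x / max(np.std(x), 1e-300)


def _slow_modulator(n: int, fs: float, rng: np.random.Generator, cutoff: float = 0.5) -> np.ndarray:
    b, a = butter(4, cutoff / (fs / 2.0), btype="lowpass")
    g = filtfilt(b, a, rng.standard_normal(n))
    return (g - g.mean()) / max(np.std(g), 1e-300)


#: log-amplitude scale of the planted envelope modulation
ENVELOPE_LOG_SD = 0.6


def _lognormal_mixing_rho(rho: float, sigma: float = ENVELOPE_LOG_SD) -> float:
    """Gaussian mixing weight whose log-normal image has correlation rho.

    If the log-amplitudes are bivariate normal with correlation r and
    variance sigma^2, the amplitudes exp(sigma g) have correlation
    (exp(r sigma^2) - 1) / (exp(sigma^2) - 1); inverting that map keeps
    the *measured* envelope correlation on target rather than the latent
    Gaussian one.
    """
    return float(np.log1p(abs(rho) * np.expm1(sigma**2)) / sigma**2)


def _flat_carrier(
    carrier: np.ndarray, band: FrequencyBand, fs: float, n_iter: int = 4
) -> np.ndarray:
    """Band-limited carrier with (near-)constant analytic envelope.

    Dividing by the envelope flattens amplitude but spreads the spectrum;
    re-bandpassing restores band limits but re-introduces amplitude
    fluctuation.  A few alternations converge to an almost
    constant-envelope band-limited signal, so a planted slow envelope
    survives measurement undiluted by the carrier's own Rayleigh-like
    amplitude fluctuations.
    """
    nyq = fs / 2.0
    b, a = butter(4, [band.low / nyq, band.high / nyq], btype="bandpass")
    x = carrier
    for _ in range(n_iter):
        z = hilbert(x)
        x = np.real(z) / np.maximum(np.abs(z), 1e-12)
        x = filtfilt(b, a, x)
    return x / max(np.std(x), 1e-300)


def gen_coupled_timeseries(
    specs: Sequence[CouplingSpec], P: int, seed: int = 0
) -> RegionalTimeSeries:
    """Multi-band oscillatory series with planted phase/envelope coupling.

    Each region's signal sums one unit-variance band-limited noise
    carrier per band.  Phase-lag edges share a carrier rotated by a fixed
    angle in the analytic domain; envelope edges share a slow log-normal
    amplitude modulator on independent carriers.  Bands must not overlap
    and must agree on duration and sampling rate.  Child random streams
    are spawned per band, in the order given.
    """
    specs = list(specs)
    if not specs:
        raise ValidationError("need at least one coupling spec")
    fs = specs[0].sampling_rate
    dur = specs[0].duration_s
    for s in specs:
        if s.sampling_rate != fs or s.duration_s != dur:
            raise ValidationError("all coupling specs must share duration and rate")
    bands = sorted(specs, key=lambda s: s.band.low)
    for b1, b2 in zip(bands, bands[1:]):
        if b2.band.low < b1.band.high:
            raise ValidationError(
                f"bands {b1.band.name} and {b2.band.name} overlap"
            )
    for s in specs:
        for i, j, _ in s.phase_lag_edges + s.envelope_corr_edges:
            if not (0 <= i < P and 0 <= j < P):
                raise ValidationError(f"edge ({i}, {j}) outside 0..{P - 1}")
    n = int(round(dur * fs))
    children = np.random.SeedSequence(seed).spawn(len(specs))
    data = np.zeros((P, n))
    for s, child in zip(specs, children):
        rng = np.random.default_rng(child)
        carriers = np.stack([_bandlimited_noise(s.band, n, fs, rng) for _ in range(P)])
        for i, j, lag in s.phase_lag_edges:
            z = hilbert(carriers[i])
            carriers[j] = np.real(z * np.exp(-1j * lag))  # phase_i - phase_j = lag
        # modulator bandwidth: fast enough for stable correlation
        # estimates over the recording, slow relative to the band
        cutoff = min(2.0, s.band.low / 2.0)
        for i, j, rho in s.envelope_corr_edges:
            common = _slow_modulator(n, fs, rng, cutoff=cutoff)
            sgn = np.sign(rho) if rho != 0 else 1.0
            r_mix = _lognormal_mixing_rho(rho)
            for r, flip in ((i, 1.0), (j, sgn)):
                private = _slow_modulator(n, fs, rng, cutoff=cutoff)
                g = np.sqrt(r_mix) * flip * common + np.sqrt(1 - r_mix) * private
                env = np.exp(ENVELOPE_LOG_SD * g)
                sig = env * _flat_carrier(carriers[r], s.band, fs)
                carriers[r] = sig / max(np.std(sig), 1e-300)
        data += carriers
    return RegionalTimeSeries(data=data, sampling_rate=fs)


@dataclass
class RecoveryReport:
    """Per-replicate recovery errors plus summary quantiles."""

    replicates: pd.DataFrame
    summary: dict
    n_coefficients_paper: int
    n_coefficients_fitted: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RecoveryReport: {len(self.replicates)} replicates, "
            f"{self.n_coefficients_paper} coefficients (gradient+Hessian count); "
            f"median max-rel-error {self.summary['rel_error_median']:.3g}, "
            f"median R^2 {self.summary['r2_median']:.4f}"
        )


def recovery_experiment(
    spec: SyntheticSpec,
    n_replicates: int = 20,
    seeds: Sequence[int] | None = None,
) -> RecoveryReport:
    """Repeatedly generate, plant, fit — and measure coefficient recovery.

    Each replicate draws a fresh stack and noise realisation (seeds
    ``spec.seed + r`` unless given), fits the model matching the planted
    structure, and records the maximum relative coefficient error
    ``max|theta_hat - theta| / max|theta|`` and the R-squared.
    """
    if seeds is None:
        seeds = [spec.seed + r for r in range(n_replicates)]
    rows = []
    for s in seeds:
        rep = SyntheticSpec(
            P=spec.P,
            D=spec.D,
            planted_a=spec.planted_a,
            planted_b=spec.planted_b,
            planted_c=spec.planted_c,
            noise_sd=spec.noise_sd,
            structure=spec.structure,
            seed=int(s),
        )
        stack = gen_stack(rep)
        target = plant_target(stack, rep)
        a, b, c = rep.coefficients()
        model = TaylorNetworkModel(target, stack, rep.fit_spec)
        res = model.fit()
        theta = np.concatenate(
            [a, [b[m, n] for (m, n) in model.terms.quad_pairs], [c]]
        )
        err = np.max(np.abs(res.params.to_numpy() - theta)) / max(
            np.max(np.abs(theta)), 1e-300
        )
        rows.append({"seed": int(s), "rel_error": float(err), "r2": res.rsquared})
    frame = pd.DataFrame(rows)
    summary = {
        "rel_error_median": float(frame["rel_error"].median()),
        "rel_error_q90": float(frame["rel_error"].quantile(0.9)),
        "r2_median": float(frame["r2"].median()),
        "r2_min": float(frame["r2"].min()),
    }
    counts_paper = count_coefficients(spec.D, "paper")
    counts_fitted = count_coefficients(spec.D, "fitted")
    return RecoveryReport(
        replicates=frame,
        summary=summary,
        n_coefficients_paper=counts_paper.total,
        n_coefficients_fitted=counts_fitted.total,
    )
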