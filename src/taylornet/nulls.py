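"""Permutation inference with spectrum-preserving pseudo-matrices.

The null model for "does the electrophysiological stack predict the
haemodynamic matrix" replaces each genuine adjacency matrix with a
*pseudo-matrix*: the eigenvalue spectrum is kept, but each eigenvector's
entry sequence is scrambled by Fourier phase randomization and the set
re-orthonormalized before reconstruction.  The surrogate therefore shares
the mathematical structure of the original (symmetry, spectrum, hence
trace zero) while carrying no genuine region-to-region connectivity.

Three hypothesis tests use these surrogates:

* variance test — is the R-squared of the real fit larger than under the
  null? (one per model variant, Bonferroni across the five variants)
* gradient test — does R-squared grow faster with model complexity than
  it does for surrogates?
* increment test — is each step up the nested model ladder a larger
  R-squared jump than for surrogates? (Bonferroni across the 3 steps)

plus a subject-swap test at the individual level and a Mann-Whitney U
comparison between coupling metrics.  All permutation p-values use the
add-one rule (1 + exceedances) / (1 + n_perm), so p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConnectivityMatrix, FrequencyBand, MatrixStack, ValidationError
from .taylor import ModelSpec, TaylorNetworkResults, fit_taylor

__all__ = [
    "PermutationResult",
    "RegionalContribution",
    "pseudo_matrix",
    "pseudo_stack",
    "randomized_reconstruction",
    "test_variance_explained",
    "test_gradient",
    "test_increments",
    "subject_swap_test",
    "mann_whitney_u",
    "regional_contribution",
    "BONFERRONI_MODELS",
    "BONFERRONI_INCREMENTS",
]

#: Bonferroni-corrected significance thresholds: five model variants for
#: the variance test, three complexity increments for the increment test.
BONFERRONI_MODELS = 0.05 / 5
BONFERRONI_INCREMENTS = 0.05 / 3


@dataclass
class PermutationResult:
    """Observed statistic vs an empirical permutation null."""

    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    statistic_name: str
    threshold: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold

    def null_summary(self) -> dict:
        q = np.quantile(self.null_values, [0.025, 0.5, 0.95, 0.975])
        return {
            "mean": float(np.mean(self.null_values)),
            "sd": float(np.std(self.null_values, ddof=1)) if self.n_perm > 1 else 0.0,
            "q02.5": float(q[0]),
            "median": float(q[1]),
            "q95": float(q[2]),
            "q97.5": float(q[3]),
        }


def _perm_p(observed: float, null_values: np.ndarray) -> float:
    return (1.0 + int(np.sum(null_values >= observed))) / (1.0 + null_values.size)


def _phase_randomize(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize the Fourier phases of a real sequence, keeping amplitudes.

    The DC component (and the Nyquist bin for even length) keep their
    original — necessarily real — phase so the inverse transform is real.
    """
    n = u.size
    spec = np.fft.rfft(u)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.size)
    phases[0] = np.angle(spec[0])
    if n % 2 == 0:
        phases[-1] = np.angle(spec[-1])
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def randomized_reconstruction(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """U' L U'^T with phase-randomized, re-orthonormalized eigenvectors.

    The orthonormal similarity preserves the eigenvalue multiset exactly;
    the diagonal is *not* yet zeroed here.
    """
    lam, u = np.linalg.eigh(weights)
    u_rand = np.column_stack([_phase_randomize(u[:, j], rng) for j in range(u.shape[1])])
    q, r = np.linalg.qr(u_rand)
    # fix QR sign ambiguity for determinism across BLAS builds
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    recon = (q * lam) @ q.T
    return 0.5 * (recon + recon.T)


def pseudo_matrix(
    w: ConnectivityMatrix, seed: int | np.random.Generator = 0
) -> ConnectivityMatrix:
    """Spectrum-preserving surrogate of a connectivity matrix.

    Eigendecompose W = U L U^T, phase-randomize each eigenvector's entry
    sequence, re-orthonormalize the randomized set (QR), reconstruct
    U' L U'^T and zero the diagonal.  Before diagonal zeroing the
    eigenvalue multiset is exactly preserved (orthonormal similarity).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.max(np.abs(w.weights - w.weights.T)) > 1e-12:
        raise ValidationError("pseudo_matrix requires a symmetric input")
    recon = randomized_reconstruction(w.weights, rng)
    np.fill_diagonal(recon, 0.0)
    return ConnectivityMatrix(
        recon,
        metric=w.metric,
        band=w.band,
        region_labels=list(w.region_labels),
        check_range=False,
    )


def pseudo_stack(
    stack: MatrixStack, seed: int | np.random.Generator = 0
) -> MatrixStack:
    """One pseudo-matrix per stack member, each with its own random draw."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MatrixStack([pseudo_matrix(m, rng) for m in stack])


def _check_nperm(n_perm: int) -> None:
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")


def test_variance_explained(
    target: ConnectivityMatrix,
    stack: MatrixStack,
    spec: ModelSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the variance a model explains (one-sided).

    The observed statistic is the R-squared of the real fit; each null
    draw refits the identical model on a fresh pseudo-stack.  The
    reported threshold is Bonferroni-corrected for the five model
    variants tested in a full analysis.
    """
    _check_nperm(n_perm)
    observed = fit_taylor(target, stack, spec).rsquared
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            fit_taylor(target, pseudo_stack(stack, rng), spec).rsquared
            for _ in range(n_perm)
        ]
    )
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=_perm_p(observed, null),
        n_perm=n_perm,
        seed=seed,
        statistic_name=f"R2[{spec.variant}]",
        threshold=BONFERRONI_MODELS,
    )


def _r2_sequence(
    target: ConnectivityMatrix, stack: MatrixStack, specs: list[ModelSpec]
) -> np.ndarray:
    return np.array([fit_taylor(target, stack, s).rsquared for s in specs])


def _slope(values: np.ndarray) -> float:
    idx = np.arange(1, values.size + 1, dtype=float)
    return float(np.polyfit(idx, values, 1)[0])


def test_gradient(
    target: ConnectivityMatrix,
    stack: MatrixStack,
    ordered_specs: list[ModelSpec],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Rate of R-squared improvement across the model ladder vs surrogates.

    Observed statistic: least-squares slope of R-squared against model
    index.  Surrogate slopes are also positive on average (extra terms
    always help), so the test asks whether the *rate* seen in real data
    is extreme, not merely positive.  One pseudo-stack is drawn per
    iteration and shared across the ladder, preserving within-iteration
    nesting.
    """
    _check_nperm(n_perm)
    if len(ordered_specs) < 2:
        raise ValidationError("gradient test needs >= 2 ordered models")
    observed = _slope(_r2_sequence(target, stack, ordered_specs))
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            _slope(_r2_sequence(target, pseudo_stack(stack, rng), ordered_specs))
            for _ in range(n_perm)
        ]
    )
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=_perm_p(observed, null),
        n_perm=n_perm,
        seed=seed,
        statistic_name="dR2/dmodel",
        threshold=0.05,
    )


def test_increments(
    target: ConnectivityMatrix,
    stack: MatrixStack,
    ordered_specs: list[ModelSpec],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Per-step R-squared increments along the nested ladder vs surrogates.

    For each consecutive model pair the observed statistic is
    delta-R-squared; nulls come from the same increments on pseudo-stacks
    (one stack per iteration, shared across the ladder).  Thresholds are
    Bonferroni-corrected for the three increments.
    """
    _check_nperm(n_perm)
    if len(ordered_specs) < 2:
        raise ValidationError("increment test needs >= 2 ordered models")
    obs_seq = _r2_sequence(target, stack, ordered_specs)
    obs_inc = np.diff(obs_seq)
    rng = np.random.default_rng(seed)
    null_inc = np.empty((n_perm, obs_inc.size))
    for i in range(n_perm):
        null_inc[i] = np.diff(_r2_sequence(target, pseudo_stack(stack, rng), ordered_specs))
    results = []
    for k in range(obs_inc.size):
        results.append(
            PermutationResult(
                observed=float(obs_inc[k]),
                null_values=null_inc[:, k].copy(),
                p_value=_perm_p(float(obs_inc[k]), null_inc[:, k]),
                n_perm=n_perm,
                seed=seed,
                statistic_name=(
                    f"dR2[{ordered_specs[k].variant}->{ordered_specs[k + 1].variant}]"
                ),
                threshold=BONFERRONI_INCREMENTS,
            )
        )
    return results


def subject_swap_test(
    per_subject_targets: list[ConnectivityMatrix],
    per_subject_stacks: list[MatrixStack],
    spec: ModelSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Does a subject's own stack predict their target best?

    Observed: matched-pair R-squared per subject.  Null: R-squared of the
    subject's target against stacks drawn from *other* subjects.  A
    subject is deemed to carry subject-specific mapping information when
    the matched R-squared is extreme at the 5% level.
    """
    _check_nperm(n_perm)
    n_sub = len(per_subject_targets)
    if n_sub < 3 or len(per_subject_stacks) != n_sub:
        raise ValidationError("subject-swap test needs >= 3 matched subject pairs")
    rng = np.random.default_rng(seed)
    results = []
    for s in range(n_sub):
        observed = fit_taylor(per_subject_targets[s], per_subject_stacks[s], spec).rsquared
        others = [t for t in range(n_sub) if t != s]
        draws = rng.choice(others, size=n_perm)
        null = np.array(
            [
                fit_taylor(per_subject_targets[s], per_subject_stacks[t], spec).rsquared
                for t in draws
            ]
        )
        results.append(
            PermutationResult(
                observed=observed,
                null_values=null,
                p_value=_perm_p(observed, null),
                n_perm=n_perm,
                seed=seed,
                statistic_name=f"R2[subject {s}]",
                threshold=0.05,
            )
        )
    return results


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float, float]:
    """Mann-Whitney U with midrank ties and tie-corrected normal Z.

    Returns ``(U, Z, p)`` where U counts pairs (a > b) plus half-ties,
    Z is the tie-corrected normal deviate of U about its null mean, and
    p is the two-sided normal-approximation p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 0.0, 1.0
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


@dataclass
class RegionalContribution:
    """Edges a single band's linear model explains, thresholded by its R^2."""

    band: FrequencyBand
    r2: float
    retained_edges: list[tuple[str, str]]
    node_strength: pd.Series
    fit: TaylorNetworkResults | None = field(default=None, repr=False)


def regional_contribution(
    target: ConnectivityMatrix,
    stack: MatrixStack,
    band: FrequencyBand | str,
    metric: str,
) -> RegionalContribution:
    """Regional pattern explained by one frequency band.

    Fits the single-frequency linear model for (metric, band), keeps the
    top ``round(R^2 * E)`` predicted edges by absolute fitted weight
    (e.g. R^2 = 0.1 retains the top 10% of the E = P(P-1)/2 edges), and
    reports per-region node strength (mean fitted off-diagonal weight).
    Ties in the edge ranking break lexicographically on region labels.
    """
    band_name = band.name if isinstance(band, FrequencyBand) else band
    spec = ModelSpec("single_frequency", bands=(band_name,), metrics=(metric,))
    res = fit_taylor(target, stack, spec)
    band_obj = stack.get(metric, band_name).band
    assert band_obj is not None
    p = target.n_regions
    e = p * (p - 1) // 2
    labels = target.region_labels
    r2 = res.rsquared
    strength = pd.Series(res.fitted.sum(axis=1) / (p - 1), index=labels)
    if r2 <= 0:
        warnings.warn(f"R^2 <= 0 for band {band_name}; no edges retained")
        return RegionalContribution(band_obj, r2, [], strength, res)
    n_keep = int(round(r2 * e))
    iu = np.triu_indices(p, 1)
    edges = sorted(
        zip(-np.abs(res.fitted[iu]), (labels[i] for i in iu[0]), (labels[j] for j in iu[1]))
    )
    retained = [(li, lj) for _, li, lj in edges[:n_keep]]
    return RegionalContribution(band_obj, r2, retained, strength, res)
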