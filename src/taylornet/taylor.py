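"""Multivariate Taylor expansion of adjacency-matrix stacks.

A haemodynamic connectivity matrix V is modelled as a second-order
multivariate Taylor expansion, about zero, of the stack of
electrophysiological connectivity matrices W = (W_1, ..., W_D):

    V  ~=  sum_m a_m W_m  +  (1/2) sum_m sum_n b_mn W_m W_n  +  c (u u^T - I)

The linear terms ("direct connectivity") add up per-band adjacency
matrices; the quadratic terms ("shared connectivity") are matrix products
whose (p, q) entry is the inner product of region p's whole-brain
connectivity profile in band m with region q's profile in band n — high
when the two regions talk to the same places.  Cross terms (m != n)
compare profiles across bands.  The constant c offsets every off-diagonal
element; the diagonal is outside the model (zero throughout).

Because the products W_m W_n can be precomputed, the expansion is linear
in the unknown coefficients, so the default estimator is ordinary least
squares on the vectorized upper-triangle off-diagonal elements — the
deterministic optimum of the same objective an iterative non-linear
solver would minimise.  Fitting follows the statsmodels Model/Results
idiom: build a :class:`TaylorNetworkModel`, call :meth:`fit`, inspect the
returned :class:`TaylorNetworkResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConnectivityMatrix, FrequencyBand, MatrixStack, ValidationError

__all__ = [
    "ModelSpec",
    "TermList",
    "CoefficientCount",
    "SpectralDiagnostics",
    "shared_connectivity",
    "build_terms",
    "count_coefficients",
    "r_squared",
    "spectral_check",
    "TaylorNetworkModel",
    "TaylorNetworkResults",
    "fit_taylor",
    "predict",
    "fit_model_sequence",
    "best_single_frequency",
    "standard_model_sequence",
    "VARIANTS",
]

VARIANTS = ("single_frequency", "linear", "nonlinear", "nonlinear_cross", "full")


@dataclass(frozen=True)
class ModelSpec:
    """Which expansion terms to fit.

    variant
        ``single_frequency`` — one band, one metric, linear term only;
        ``linear`` — all selected bands, one metric, linear terms;
        ``nonlinear`` — linear + within-band quadratic terms;
        ``nonlinear_cross`` — linear + all quadratic terms incl. cross-band;
        ``full`` — nonlinear_cross over both coupling metrics.
    bands, metrics
        Optional subsets (by name); ``None`` means every band/metric
        present in the stack.  The development point is fixed at zero.
    """

    variant: str
    bands: tuple[str, ...] | None = None
    metrics: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.bands is not None:
            object.__setattr__(self, "bands", tuple(self.bands))
        if self.metrics is not None:
            object.__setattr__(self, "metrics", tuple(self.metrics))
        if self.variant == "single_frequency":
            if self.bands is None or len(self.bands) != 1:
                raise ValidationError("single_frequency requires exactly one band")
            if self.metrics is not None and len(self.metrics) != 1:
                raise ValidationError("single_frequency requires exactly one metric")
        if self.variant in ("linear", "nonlinear", "nonlinear_cross"):
            if self.metrics is not None and len(self.metrics) != 1:
                raise ValidationError(f"{self.variant} uses a single metric")

    @property
    def include_quadratic(self) -> bool:
        return self.variant in ("nonlinear", "nonlinear_cross", "full")

    @property
    def include_cross_terms(self) -> bool:
        return self.variant in ("nonlinear_cross", "full")

    def select(self, stack: MatrixStack) -> MatrixStack:
        """The sub-stack this spec operates on."""
        metrics = list(self.metrics) if self.metrics is not None else None
        bands = list(self.bands) if self.bands is not None else None
        sub = stack.subset(metrics=metrics, band_names=bands)
        if self.variant == "single_frequency" and sub.D != 1:
            raise ValidationError(
                f"single_frequency selected {sub.D} matrices; specify one metric"
            )
        if self.variant == "full" and len(sub.metrics) < 2:
            raise ValidationError("full model requires both coupling metrics in the stack")
        return sub


def _matrix_label(m: ConnectivityMatrix) -> str:
    band = m.band.name if m.band is not None else "broadband"
    return f"{m.metric}:{band}"


def shared_connectivity(wm: ConnectivityMatrix, wn: ConnectivityMatrix) -> np.ndarray:
    """Matrix product W_m W_n: overlap of whole-brain connectivity profiles.

    Entry (p, q) is the inner product of column p of ``wm`` with column q
    of ``wn``; for ``wm is wn`` the diagonal holds the un-normalised
    variance of each region's connectivity profile.
    """
    if wm.n_regions != wn.n_regions or wm.region_labels != wn.region_labels:
        raise ValidationError("shared_connectivity requires matching regions")
    return wm.weights @ wn.weights


@dataclass
class TermList:
    """Regressors of one model: matrices plus their vectorized design.

    ``design`` is E x K over the E = P(P-1)/2 strictly-upper-triangular
    elements; the last column is the constant off-diagonal offset.
    """

    labels: list[str]
    matrices: list[np.ndarray]  # excludes the offset regressor
    design: np.ndarray
    region_labels: list[str]
    spec: ModelSpec
    stack_keys: list[tuple[str, str | None]]
    n_linear: int
    quad_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.design.shape[1]

    @property
    def E(self) -> int:
        return self.design.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


def _quadratic_regressor(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    """Symmetrized product 0.5 (W_a W_b + W_b W_a); equals W_a^2 when a is b."""
    prod = wa @ wb
    return 0.5 * (prod + prod.T)


def build_terms(stack: MatrixStack, spec: ModelSpec) -> TermList:
    """Construct the regressor list of Eq-style expansion terms.

    Linear regressors are the selected W_m.  Quadratic regressors are one
    per *unordered* index pair: the symmetric Hessian of a Taylor
    expansion makes b_mn = b_nm without loss of generality on a symmetric
    target, so each pair {m, n} carries a single symmetrized product
    regressor.  A constant off-diagonal column completes the design.
    """
    sub = spec.select(stack)
    ws = [m.weights for m in sub.matrices]
    labels = [f"a[{_matrix_label(m)}]" for m in sub.matrices]
    matrices = list(ws)
    quad_pairs: list[tuple[int, int]] = []
    if spec.include_quadratic:
        mat_labels = [_matrix_label(m) for m in sub.matrices]
        for m in range(sub.D):
            for n in range(m, sub.D):
                if m != n and not spec.include_cross_terms:
                    continue
                # cross terms only between different bands/metrics of the
                # same selection; m == n gives W_m squared
                quad_pairs.append((m, n))
                matrices.append(_quadratic_regressor(ws[m], ws[n]))
                labels.append(f"b[{mat_labels[m]},{mat_labels[n]}]")
    p = sub.n_regions
    iu = np.triu_indices(p, 1)
    cols = [mat[iu] for mat in matrices] + [np.ones(iu[0].size)]
    labels = labels + ["c"]
    design = np.column_stack(cols)
    return TermList(
        labels=labels,
        matrices=matrices,
        design=design,
        region_labels=sub.region_labels,
        spec=spec,
        stack_keys=sub.keys,
        n_linear=sub.D,
        quad_pairs=quad_pairs,
    )


class CoefficientCount(NamedTuple):
    linear: int
    quadratic: int
    total: int


def count_coefficients(
    spec_or_d: "ModelSpec | int",
    convention: str = "paper",
    n_matrices: int | None = None,
) -> CoefficientCount:
    """Number of Taylor coefficients for a model.

    ``paper`` counts every gradient entry (D) plus every Hessian entry
    (D x D when cross terms are in play), the convention under which the
    full ten-matrix model has 110 coefficients.  ``fitted`` counts the
    distinct coefficients actually estimated with a symmetrized Hessian:
    D + D(D+1)/2.  The off-diagonal offset is excluded from both.

    An integer argument counts a complete second-order expansion in that
    many matrices; a :class:`ModelSpec` respects its term flags (with
    ``n_matrices`` giving the selection size, default from the band and
    metric subsets).
    """
    if convention not in ("paper", "fitted"):
        raise ValidationError("convention must be 'paper' or 'fitted'")
    if isinstance(spec_or_d, int):
        d = spec_or_d
        quad, cross = True, True
    else:
        spec = spec_or_d
        quad, cross = spec.include_quadratic, spec.include_cross_terms
        if n_matrices is not None:
            d = n_matrices
        elif spec.bands is not None:
            n_metrics = len(spec.metrics) if spec.metrics is not None else 1
            d = len(spec.bands) * n_metrics
        else:
            raise ValidationError(
                "cannot infer the matrix count; pass n_matrices explicitly"
            )
    if d < 1:
        raise ValidationError("need at least one matrix")
    linear = d
    if not quad:
        quadratic = 0
    elif not cross:
        quadratic = d
    elif convention == "paper":
        quadratic = d * d
    else:
        quadratic = d * (d + 1) // 2
    return CoefficientCount(linear, quadratic, linear + quadratic)


def r_squared(v: np.ndarray | ConnectivityMatrix, vhat: np.ndarray | ConnectivityMatrix) -> float:
    """Coefficient of determination over upper-triangle off-diagonal entries.

    1 - SSE/SST with SST about the mean of the target's elements.
    """
    vw = v.weights if isinstance(v, ConnectivityMatrix) else np.asarray(v, dtype=float)
    vh = vhat.weights if isinstance(vhat, ConnectivityMatrix) else np.asarray(vhat, dtype=float)
    if vw.shape != vh.shape:
        raise ValidationError("shape mismatch in r_squared")
    iu = np.triu_indices(vw.shape[0], 1)
    y, yhat = vw[iu], vh[iu]
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValidationError("target has zero variance over off-diagonal elements")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


@dataclass
class SpectralDiagnostics:
    """Eigen-spectra of the stack, for the convergence sanity check.

    A zero diagonal forces trace(W) = 0, so the eigenvalues sum to zero;
    when the spectral radius stays below the (unknown) convergence radius
    the expansion about zero is well behaved.  Spectral radius >= 1 is
    flagged as a warning, not an error — the radius itself cannot be
    estimated from data.
    """

    labels: list[str]
    eigenvalues: list[np.ndarray]
    max_abs_eigenvalue: np.ndarray
    trace: np.ndarray

    @property
    def warnings(self) -> list[str]:
        return [
            lbl
            for lbl, lam in zip(self.labels, self.max_abs_eigenvalue)
            if lam >= 1.0
        ]


def spectral_check(stack: MatrixStack) -> SpectralDiagnostics:
    labels, eigs, maxabs, traces = [], [], [], []
    for m in stack:
        lam = m.eigenvalues()
        labels.append(_matrix_label(m))
        eigs.append(lam)
        maxabs.append(float(np.max(np.abs(lam))))
        traces.append(float(np.trace(m.weights)))
    diag = SpectralDiagnostics(
        labels=labels,
        eigenvalues=eigs,
        max_abs_eigenvalue=np.array(maxabs),
        trace=np.array(traces),
    )
    for lbl in diag.warnings:
        warnings.warn(f"spectral radius >= 1 for {lbl}; expansion may diverge")
    return diag


class TaylorNetworkModel:
    """Second-order Taylor expansion of a matrix stack, fitted to a target.

    Parameters
    ----------
    target : ConnectivityMatrix
        The haemodynamic connectivity matrix V.
    stack : MatrixStack
        Electrophysiological connectivity matrices W_1..W_D.
    spec : ModelSpec
        Which bands/metrics/terms to include.

    Examples
    --------
    >>> model = TaylorNetworkModel(v, stack, ModelSpec("linear", metrics=("AEC",)))
    >>> res = model.fit()
    >>> res.rsquared, res.a
    """

    def __init__(self, target: ConnectivityMatrix, stack: MatrixStack, spec: ModelSpec):
        if target.region_labels != stack.region_labels:
            raise ValidationError("target and stack must share region labels/order")
        self.target = target
        self.stack = stack
        self.spec = spec
        self.terms = build_terms(stack, spec)
        if self.terms.K >= self.terms.E:
            raise ValidationError(
                f"under-determined fit: K={self.terms.K} coefficients for "
                f"E={self.terms.E} off-diagonal elements"
            )
        iu = np.triu_indices(target.n_regions, 1)
        self._iu = iu
        self.endog = target.weights[iu]

    @classmethod
    def from_matrices(
        cls,
        target: np.ndarray,
        matrices: Sequence[np.ndarray],
        spec: ModelSpec | str = "linear",
        region_labels: list[str] | None = None,
        bands: Sequence[FrequencyBand] | None = None,
        metric: str = "generic",
    ) -> "TaylorNetworkModel":
        """Convenience constructor from bare arrays."""
        mats = [
            ConnectivityMatrix(
                w,
                metric=metric,
                band=bands[i] if bands is not None else None,
                region_labels=region_labels or [],
            )
            for i, w in enumerate(matrices)
        ]
        stack = MatrixStack(mats)
        tgt = ConnectivityMatrix(target, metric="generic", region_labels=stack.region_labels)
        if isinstance(spec, str):
            spec = ModelSpec(spec)
        return cls(tgt, stack, spec)

    def fit(self, method: str = "ols") -> "TaylorNetworkResults":
        """Estimate the coefficients.

        ``ols`` solves the (linear-in-coefficients) least-squares problem
        directly and deterministically.  ``iterative`` runs a
        Levenberg-Marquardt style non-linear solver on the identical
        objective; it converges to the same optimum and exists for parity
        with iterative fitting pipelines.
        """
        x, y = self.terms.design, self.endog
        if method == "ols":
            theta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            if rank < self.terms.K:
                deficient = self._deficient_labels(x)
                warnings.warn(
                    "rank-deficient design (minimum-norm solution); "
                    f"suspect regressors: {deficient}"
                )
        elif method == "iterative":
            from scipy.optimize import least_squares

            sol = least_squares(lambda t: x @ t - y, x0=np.zeros(self.terms.K))
            theta, rank = sol.x, self.terms.K
        else:
            raise ValidationError(f"unknown fit method {method!r}")
        return TaylorNetworkResults(self, theta, rank)

    def _deficient_labels(self, x: np.ndarray) -> list[str]:
        # columns nearly in the span of the preceding ones
        bad = []
        for k in range(1, x.shape[1]):
            sub = x[:, :k]
            resid = x[:, k] - sub @ np.linalg.lstsq(sub, x[:, k], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(x[:, k]), 1e-300):
                bad.append(self.terms.labels[k])
        return bad


class TaylorNetworkResults:
    """Fit results: coefficients, uncertainties, diagnostics, prediction.

    Attributes
    ----------
    params : pandas.Series
        All coefficients keyed by term label (``a[...]``, ``b[...]``, ``c``).
    a, b, c
        Linear coefficients (Series), symmetric quadratic coefficient
        table (DataFrame, ``b_mn = b_nm``), and the off-diagonal offset.
    fitted : ndarray
        The reconstructed matrix V-hat (symmetric, zero diagonal; entries
        are *not* clipped to [-1, 1] — see ``n_out_of_range``).
    rsquared : float
    """

    def __init__(self, model: TaylorNetworkModel, theta: np.ndarray, rank: int):
        self.model = model
        self.spec = model.spec
        terms = model.terms
        self.params = pd.Series(theta, index=terms.labels)
        self.rank = int(rank)
        self.df_resid = terms.E - self.rank

        yhat = terms.design @ theta
        resid = model.endog - yhat
        self.ssr = float(resid @ resid)
        centred = model.endog - model.endog.mean()
        sst = float(centred @ centred)
        if sst == 0:
            raise ValidationError("target has zero off-diagonal variance")
        self.rsquared = 1.0 - self.ssr / sst

        p = terms.n_regions
        fitted = np.zeros((p, p))
        iu = model._iu
        fitted[iu] = yhat
        self.fitted = fitted + fitted.T
        residual = np.zeros((p, p))
        residual[iu] = resid
        self.residual = residual + residual.T

        sigma2 = self.ssr / max(self.df_resid, 1)
        xtx = terms.design.T @ terms.design
        self.cov_params = sigma2 * np.linalg.pinv(xtx)
        self.bse = pd.Series(np.sqrt(np.diag(self.cov_params)), index=terms.labels)
        self.scale = sigma2

    # ---- coefficient views -------------------------------------------------
    @property
    def a(self) -> pd.Series:
        terms = self.model.terms
        return self.params.iloc[: terms.n_linear]

    @property
    def b(self) -> pd.DataFrame:
        """Symmetric table of quadratic coefficients (NaN where not fitted)."""
        terms = self.model.terms
        names = [lbl[2:-1] for lbl in terms.labels[: terms.n_linear]]
        tbl = pd.DataFrame(np.nan, index=names, columns=names)
        for (m, n), val in zip(
            terms.quad_pairs,
            self.params.iloc[terms.n_linear : terms.n_linear + len(terms.quad_pairs)],
        ):
            tbl.iloc[m, n] = val
            tbl.iloc[n, m] = val
        return tbl

    @property
    def c(self) -> float:
        return float(self.params.iloc[-1])

    @property
    def r2(self) -> float:  # spec-friendly alias
        return self.rsquared

    @property
    def n_out_of_range(self) -> int:
        """Fitted off-diagonal entries outside [-1, 1] (not clipped)."""
        iu = self.model._iu
        vals = self.fitted[iu]
        return int(np.sum((vals < -1) | (vals > 1)))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided CIs from the classical linear-model covariance."""
        tval = sps.t.ppf(1 - alpha / 2, max(self.df_resid, 1))
        lo = self.params - tval * self.bse
        hi = self.params + tval * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def ci(self) -> pd.DataFrame:
        return self.conf_int()

    # ---- prediction --------------------------------------------------------
    def predict(self, stack: MatrixStack | None = None) -> np.ndarray:
        """Apply the estimated expansion to a (new) stack.

        Returns the symmetric zero-diagonal matrix
        sum a_m W_m + sum b_mn sym(W_m W_n) + c (u u^T - I).
        """
        if stack is None:
            return self.fitted.copy()
        terms = build_terms(stack, self.spec)
        if terms.labels != self.model.terms.labels:
            raise ValidationError("stack incompatible with the fitted model terms")
        p = terms.n_regions
        iu = np.triu_indices(p, 1)
        yhat = terms.design @ self.params.to_numpy()
        out = np.zeros((p, p))
        out[iu] = yhat
        return out + out.T

    def refit(self) -> "TaylorNetworkResults":
        """Fit the model to its own fitted matrix (idempotence check)."""
        tgt = ConnectivityMatrix(
            self.fitted - np.diag(np.diag(self.fitted)),
            metric="generic",
            region_labels=self.model.stack.region_labels,
        )
        return TaylorNetworkModel(tgt, self.model.stack, self.spec).fit()

    def summary(self) -> str:
        """Plain-text coefficient table in the statsmodels spirit."""
        ci = self.conf_int()
        lines = [
            "Taylor network expansion results",
            "=" * 64,
            f"variant: {self.spec.variant}    regions: {self.model.terms.n_regions}"
            f"    matrices: {self.model.terms.n_linear}",
            f"elements fitted (upper off-diag): {self.model.terms.E}"
            f"    coefficients: {self.model.terms.K}",
            f"R^2: {self.rsquared:.4f}    resid SS: {self.ssr:.4g}"
            f"    out-of-range fitted: {self.n_out_of_range}",
            "-" * 64,
            f"{'term':<28}{'coef':>10}{'se':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for lbl in self.params.index:
            lines.append(
                f"{lbl:<28}{self.params[lbl]:>10.4f}{self.bse[lbl]:>10.4f}"
                f"{ci.loc[lbl, 'lower']:>10.4f}{ci.loc[lbl, 'upper']:>10.4f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_fit(self, ax=None):  # pragma: no cover - visual aid
        """Scatter of target vs fitted off-diagonal elements."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        iu = self.model._iu
        ax.scatter(self.model.target.weights[iu], self.fitted[iu], s=4, alpha=0.5)
        ax.set_xlabel("target connectivity")
        ax.set_ylabel("fitted connectivity")
        ax.set_title(f"{self.spec.variant}: $R^2$ = {self.rsquared:.3f}")
        return ax


def fit_taylor(
    target: ConnectivityMatrix, stack: MatrixStack, spec: ModelSpec, method: str = "ols"
) -> TaylorNetworkResults:
    """Functional one-liner: build the model and fit it."""
    return TaylorNetworkModel(target, stack, spec).fit(method=method)


def predict(fit: TaylorNetworkResults, stack: MatrixStack) -> np.ndarray:
    """Apply a fit's coefficients to a stack (module-level convenience)."""
    return fit.predict(stack)


def _is_nested(prev: TermList, cur: TermList) -> bool:
    return set(prev.labels) <= set(cur.labels)


def fit_model_sequence(
    target: ConnectivityMatrix,
    stack: MatrixStack,
    specs: Sequence[ModelSpec],
    method: str = "ols",
) -> list[TaylorNetworkResults]:
    """Fit a sequence of progressively richer models.

    For genuinely nested regressor sets the R-squared sequence is
    non-decreasing by construction; a numerical violation beyond 1e-10 or
    a non-nested sequence raises a warning rather than an error.
    """
    fits: list[TaylorNetworkResults] = []
    for spec in specs:
        fits.append(fit_taylor(target, stack, spec, method=method))
    for prev, cur in zip(fits, fits[1:]):
        if _is_nested(prev.model.terms, cur.model.terms):
            if cur.rsquared < prev.rsquared - 1e-10:
                warnings.warn(
                    "R^2 decreased across nested models "
                    f"({prev.rsquared} -> {cur.rsquared}); numerical trouble"
                )
        else:
            warnings.warn(
                f"models {prev.spec.variant} -> {cur.spec.variant} are not nested; "
                "monotone R^2 not guaranteed"
            )
    return fits


def best_single_frequency(
    target: ConnectivityMatrix, stack: MatrixStack, metric: str
) -> tuple[str, TaylorNetworkResults]:
    """Single-band linear model with the highest R-squared for one metric."""
    best: tuple[str, TaylorNetworkResults] | None = None
    for m in stack:
        if m.metric != metric or m.band is None:
            continue
        spec = ModelSpec("single_frequency", bands=(m.band.name,), metrics=(metric,))
        res = fit_taylor(target, stack, spec)
        if best is None or res.rsquared > best[1].rsquared:
            best = (m.band.name, res)
    if best is None:
        raise ValidationError(f"no banded matrices with metric {metric!r} in stack")
    return best


def standard_model_sequence(
    target: ConnectivityMatrix, stack: MatrixStack, metric: str
) -> list[ModelSpec]:
    """The nested four-model ladder for one metric.

    Best single frequency (chosen by maximal R-squared over the stack's
    bands), then linear, nonlinear and nonlinear_cross over all bands.
    """
    band, _ = best_single_frequency(target, stack, metric)
    return [
        ModelSpec("single_frequency", bands=(band,), metrics=(metric,)),
        ModelSpec("linear", metrics=(metric,)),
        ModelSpec("nonlinear", metrics=(metric,)),
        ModelSpec("nonlinear_cross", metrics=(metric,)),
    ]
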