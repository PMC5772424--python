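"""Approximate Bayesian computation: model choice and parameter estimation.

The substrate is a :class:`ReferenceTable` of simulations — one row per
simulated dataset holding the model label, the drawn parameters and the
summary-statistic vector.  Against an observed summary vector the module
provides

* rejection sampling (MAD-standardized Euclidean distance, fixed tolerance),
* posterior model probabilities by retained-count proportions and by
  weighted multinomial logistic regression, with Bayes factors,
* a marginal-density p-value (kernel density over the retained statistics;
  the fraction of retained simulations whose density falls below the
  observed point's — a low value flags a model unable to produce the
  observed statistics),
* local-linear regression adjustment of parameters with heteroscedasticity
  correction, on the scale of each parameter's prior (log10 for loguniform
  priors), and
* weighted posterior summaries: 5% quantile, mean, median, KDE mode and the
  95% highest-posterior-density interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .demography import ModelSpec


class LayoutMismatchError(ValueError):
    pass


@dataclass
class ReferenceTable:
    """Rows of (model label, parameters, summary statistics)."""

    models: np.ndarray  # str per row
    params: pd.DataFrame  # NaN where a parameter does not apply to the model
    stats: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.models = np.asarray(self.models)
        if not (len(self.models) == len(self.params) == len(self.stats)):
            raise ValueError("row count mismatch between labels/params/stats")
        if len(self.models) == 0:
            raise ValueError("empty reference table")

    @property
    def n_rows(self) -> int:
        return len(self.models)

    @property
    def model_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.models:
            seen.setdefault(str(m))
        return tuple(seen)

    def subset(self, mask: np.ndarray) -> "ReferenceTable":
        return ReferenceTable(self.models[mask],
                              self.params.iloc[mask].reset_index(drop=True),
                              self.stats.iloc[mask].reset_index(drop=True),
                              dict(self.meta))


@dataclass
class Standardization:
    """MAD scales for a table's statistics; zero-MAD columns are dropped."""

    columns: tuple[str, ...]
    scales: np.ndarray


def _as_vector(observed, columns) -> np.ndarray:
    if isinstance(observed, pd.Series):
        missing = [c for c in columns if c not in observed.index]
        extra = [c for c in observed.index if c not in columns]
        if missing or extra:
            raise LayoutMismatchError(
                f"summary layout mismatch; missing from observed: {missing}, "
                f"not in table: {extra}")
        return observed[list(columns)].to_numpy(float)
    arr = np.asarray(observed, dtype=float)
    if arr.shape != (len(columns),):
        raise LayoutMismatchError(
            f"observed vector has shape {arr.shape}, table has "
            f"{len(columns)} statistics")
    return arr


def standardization(table: ReferenceTable) -> Standardization:
    cols = tuple(table.stats.columns)
    mat = table.stats.to_numpy(float)
    scales = sps.median_abs_deviation(mat, axis=0)
    keep = scales > 0
    if not np.all(keep):
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(
            "dropping zero-MAD summary statistics: " + ", ".join(dropped))
    return Standardization(tuple(c for c, k in zip(cols, keep) if k),
                           scales[keep])


def standardize_and_distance(table: ReferenceTable, observed,
                             std: Standardization | None = None) -> np.ndarray:
    """Euclidean distance of every row to the observed vector, after scaling
    each statistic by its median absolute deviation across the table."""
    obs = _as_vector(observed, tuple(table.stats.columns))
    if std is None:
        std = standardization(table)
    keep = [table.stats.columns.get_loc(c) for c in std.columns]
    mat = table.stats.to_numpy(float)[:, keep] / std.scales
    vec = obs[keep] / std.scales
    return np.sqrt(((mat - vec) ** 2).sum(axis=1))


@dataclass
class RetainedSet:
    """The closest-simulation subset used for model choice and estimation."""

    table: ReferenceTable
    indices: np.ndarray  # into the table, sorted by distance (stable ties)
    distances: np.ndarray  # matching `indices`
    tolerance: float
    std: Standardization
    obs_scaled: np.ndarray

    @property
    def n_retained(self) -> int:
        return len(self.indices)

    @property
    def models(self) -> np.ndarray:
        return self.table.models[self.indices]

    def stats_scaled(self) -> np.ndarray:
        keep = [self.table.stats.columns.get_loc(c) for c in self.std.columns]
        mat = self.table.stats.to_numpy(float)[np.ix_(self.indices, keep)]
        return mat / self.std.scales

    def epanechnikov_weights(self) -> np.ndarray:
        """Kernel weights in distance; 0 at the largest retained distance."""
        dmax = self.distances.max()
        if dmax == 0.0:
            return np.ones(self.n_retained)
        w = 1.0 - (self.distances / dmax) ** 2
        if w.sum() == 0.0:  # all retained rows sit exactly at dmax
            return np.ones(self.n_retained)
        return w


def reject(table: ReferenceTable, observed, tolerance: float,
           std: Standardization | None = None,
           distances: np.ndarray | None = None) -> RetainedSet:
    """Retain the ``ceil(tolerance * N)`` smallest-distance rows.

    Ties are broken by original row order (stable sort).
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    if std is None:
        std = standardization(table)
    if distances is None:
        distances = standardize_and_distance(table, observed, std)
    n_keep = math.ceil(tolerance * table.n_rows)
    order = np.argsort(distances, kind="stable")[:n_keep]
    obs = _as_vector(observed, tuple(table.stats.columns))
    keep = [table.stats.columns.get_loc(c) for c in std.columns]
    return RetainedSet(table, order, distances[order], tolerance, std,
                       obs[keep] / std.scales)


@dataclass
class ModelChoiceResult:
    """Posterior model probabilities with Bayes factors."""

    probabilities: pd.Series  # indexed by model id
    method: str
    tolerance: float
    bayes_factor_matrix: pd.DataFrame = None

    def __post_init__(self):
        if self.bayes_factor_matrix is None:
            self.bayes_factor_matrix = bayes_factors(self.probabilities)

    def bf(self, a: str, b: str) -> float:
        return float(self.bayes_factor_matrix.loc[a, b])


def model_posterior_rejection(retained: RetainedSet,
                              model_ids: tuple[str, ...] | None = None
                              ) -> pd.Series:
    """P(model) = share of the retained simulations carrying that label."""
    if retained.n_retained == 0:
        raise ValueError("empty retained set")
    ids = model_ids or retained.table.model_ids
    labels = retained.models
    probs = pd.Series({m: float(np.mean(labels == m)) for m in ids})
    return probs


def model_posterior_logistic(table: ReferenceTable, observed,
                             tolerance: float,
                             retained: RetainedSet | None = None) -> pd.Series:
    """Weighted multinomial logistic regression of model label on the
    standardized statistics over the retained set, evaluated at the
    observed point."""
    if retained is None:
        retained = reject(table, observed, tolerance)
    ids = table.model_ids
    labels = retained.models
    present = [m for m in ids if np.any(labels == m)]
    if len(present) == 1:
        return pd.Series({m: 1.0 if m == present[0] else 0.0 for m in ids})
    x = retained.stats_scaled() - retained.obs_scaled
    w = retained.epanechnikov_weights()
    pos = w > 0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # C=inf: no regularization (mirrors an unpenalized multinomial fit)
            clf = LogisticRegression(C=np.inf, max_iter=400)
            clf.fit(x[pos], labels[pos], sample_weight=w[pos])
            probs = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
        if not np.all(np.isfinite(probs)):
            raise FloatingPointError("non-finite class probabilities")
    except Exception as err:  # noqa: BLE001 - degrade gracefully
        warnings.warn(
            f"multinomial logistic regression failed ({err}); falling back "
            "to rejection proportions")
        return model_posterior_rejection(retained, ids)
    out = pd.Series(0.0, index=list(ids))
    for cls, p in zip(clf.classes_, probs):
        out[cls] = p
    return out / out.sum()


def model_choice(table: ReferenceTable, observed, tolerance: float,
                 method: str = "logistic") -> ModelChoiceResult:
    retained = reject(table, observed, tolerance)
    if method == "rejection":
        probs = model_posterior_rejection(retained)
    elif method == "logistic":
        probs = model_posterior_logistic(table, observed, tolerance, retained)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ModelChoiceResult(probs, method, tolerance)


def bayes_factors(probs: pd.Series) -> pd.DataFrame:
    """BF(i, j) = P(i) / P(j); +inf where P(j) = 0 and P(i) > 0."""
    p = probs.to_numpy(float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("probabilities must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = p[:, None] / p[None, :]
    mat[np.isnan(mat)] = 1.0  # 0/0 pairs
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=probs.index, columns=probs.index)


def marginal_density_pvalue(retained: RetainedSet,
                            observed=None) -> float:
    """Fraction of retained simulations with a lower marginal density than
    the observed point, under a Gaussian KDE over the retained standardized
    statistics."""
    if retained.n_retained == 0:
        raise ValueError("empty retained set")
    x = retained.stats_scaled()
    obs = (retained.obs_scaled if observed is None
           else _as_vector(observed, tuple(retained.table.stats.columns))[
               [retained.table.stats.columns.get_loc(c)
                for c in retained.std.columns]] / retained.std.scales)
    # drop collinear columns so the KDE covariance is invertible
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    tol = s.max() * max(centred.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < x.shape[1]:
        warnings.warn(
            f"dropping {x.shape[1] - rank} collinear statistic direction(s) "
            "for the marginal-density estimate")
        basis = vt[:rank].T
        x = centred @ basis
        obs = (obs - (retained.stats_scaled()).mean(axis=0)) @ basis
    kde = sps.gaussian_kde(x.T)
    dens_retained = kde(x.T)
    dens_obs = kde(np.atleast_2d(obs).T)[0]
    return float(np.mean(dens_retained < dens_obs))


# ---------------------------------------------------------------------------
# parameter estimation

@dataclass
class ParamTransform:
    """Estimation scale of a parameter (matches the shape of its prior)."""

    name: str
    log10: bool

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.log10(x) if self.log10 else np.asarray(x, float)

    def backward(self, y: np.ndarray) -> np.ndarray:
        return 10.0 ** y if self.log10 else y


def transforms_for(spec: ModelSpec) -> dict[str, ParamTransform]:
    return {name: ParamTransform(name, prior.kind == "loguniform")
            for name, prior in spec.priors.items()}


@dataclass
class ParameterPosterior:
    """Adjusted, weighted posterior samples per parameter (linear scale)."""

    samples: pd.DataFrame
    weights: np.ndarray
    transforms: dict[str, ParamTransform]
    out_of_prior: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if np.any(w < 0):
            raise ValueError("negative importance weights")
        self.weights = w / w.sum()


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray
         ) -> tuple[float, np.ndarray]:
    """Weighted least squares of y on [1, x]; returns (intercept, coefs)."""
    sw = np.sqrt(w)
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    return float(beta[0]), beta[1:]


def loclinear_adjust(retained: RetainedSet,
                     spec: ModelSpec,
                     param_names: tuple[str, ...] | None = None,
                     hcorr: bool = True) -> ParameterPosterior:
    """Local-linear regression adjustment with heteroscedasticity correction.

    Per parameter (on its prior scale): a weighted linear regression of the
    parameter on the standardized statistics over the retained set; adjusted
    values are the observed-point prediction plus residuals, with residuals
    rescaled by the ratio of a fitted conditional scale at the observed
    point to the scale at each retained point.  Values falling outside the
    prior support are kept and their share reported in ``out_of_prior``.
    """
    transforms = transforms_for(spec)
    if param_names is None:
        param_names = tuple(n for n in spec.param_names
                            if n in retained.table.params.columns)
    x = retained.stats_scaled() - retained.obs_scaled
    if retained.n_retained < x.shape[1] + 2:
        raise ValueError(
            f"{retained.n_retained} retained rows are too few for a local "
            f"regression on {x.shape[1]} statistics")
    w = retained.epanechnikov_weights()
    pos = w > 0
    if pos.sum() < x.shape[1] + 2:
        pos = np.ones(len(w), dtype=bool)
        w = np.ones(len(w))
    adjusted = {}
    out_of_prior = {}
    for name in param_names:
        raw = retained.table.params[name].to_numpy(float)[retained.indices]
        tr = transforms[name]
        y = tr.forward(raw)
        if np.allclose(y, y[0]):
            adj = np.full(pos.sum(), y[0])
        else:
            alpha, beta = _wls(x[pos], y[pos], w[pos])
            resid = y[pos] - (alpha + x[pos] @ beta)
            # residuals of a (p+1)-parameter weighted fit underestimate the
            # conditional spread; restore it with the usual dof correction
            wp = w[pos]
            n_eff = wp.sum() ** 2 / (wp ** 2).sum()
            dof = n_eff - (x.shape[1] + 1)
            if dof > 1:
                resid = resid * math.sqrt(n_eff / dof)
            scale = 1.0
            if hcorr and not np.allclose(resid, 0.0, atol=1e-10):
                log_r2 = np.log(resid ** 2 + 1e-300)
                a2, b2 = _wls(x[pos], log_r2, w[pos])
                fitted = a2 + x[pos] @ b2
                # guard against overfitting the variance model on few
                # retained points (it contracts the posterior tails): apply
                # the correction only when the conditional-scale regression
                # is supported by an F-test
                wp = w[pos] / w[pos].sum()
                ybar = float(wp @ log_r2)
                ss_tot = float(wp @ (log_r2 - ybar) ** 2)
                ss_res = float(wp @ (log_r2 - fitted) ** 2)
                p = x.shape[1]
                if ss_tot > 0 and dof > 1:
                    r2 = max(0.0, 1.0 - ss_res / ss_tot)
                    fstat = (r2 / p) / max((1.0 - r2) / dof, 1e-12)
                    pval = sps.f.sf(fstat, p, dof)
                    if pval < 0.05:
                        sigma = np.exp(0.5 * fitted)
                        sigma_obs = math.exp(0.5 * a2)
                        scale = np.where(sigma > 0, sigma_obs / sigma, 1.0)
            adj = alpha + resid * scale
        lin = tr.backward(adj)
        adjusted[name] = lin
        lo, hi = spec.priors[name].support
        out_of_prior[name] = float(np.mean((lin < lo) | (lin > hi)))
    return ParameterPosterior(pd.DataFrame(adjusted), w[pos], transforms,
                              out_of_prior)


# ---------------------------------------------------------------------------
# weighted summaries

def weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws)
    cum /= cum[-1]
    return float(np.interp(q, cum - 0.5 * ws / ws.sum(), xs))


def hpd_interval(x: np.ndarray, w: np.ndarray, mass: float = 0.95
                 ) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the weighted sample."""
    order = np.argsort(x)
    xs, ws = x[order], w[order] / w.sum()
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    n = len(xs)
    best = (xs[0], xs[-1])
    best_width = xs[-1] - xs[0]
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j < n and cum[j + 1] - cum[i] < mass:
            j += 1
        if j >= n:
            break
        width = xs[j] - xs[i]
        if width < best_width:
            best_width = width
            best = (xs[i], xs[j])
    return float(best[0]), float(best[1])


def weighted_mode(x: np.ndarray, w: np.ndarray,
                  bw_method: str | float = "silverman",
                  grid_size: int = 512) -> float:
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = sps.gaussian_kde(x, bw_method=bw_method, weights=w)
    grid = np.linspace(x.min(), x.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def build_reference_table(specs: dict[str, ModelSpec], n_per_model: int,
                          sample_configs: dict, rng: np.random.Generator,
                          grouping: str = "auto",
                          chunk_writer=None, chunk_size: int = 2000,
                          ) -> ReferenceTable | None:
    """Simulate ``n_per_model`` datasets per model and collect summary rows.

    ``sample_configs`` maps model id to the :class:`SampleConfig` to
    simulate under (structured models place the four statistical groups in
    four demes; unstructured ones sample all groups from the single deme,
    so the summary layout is shared).  With ``chunk_writer`` set, completed
    chunks are handed off (and dropped from memory) instead of returning an
    in-memory table — memory use is then constant in the row count.
    """
    from .coalescent import simulate_dataset  # deferred: numba import cost
    from .demography import draw_params
    from .sumstats import microsat_sumstats

    labels: list[str] = []
    param_rows: list[dict] = []
    stat_rows: list[pd.Series] = []
    meta = {"n_per_model": n_per_model, "models": ",".join(specs)}

    def flush():
        nonlocal labels, param_rows, stat_rows
        if not labels:
            return
        chunk = ReferenceTable(np.array(labels),
                               pd.DataFrame(param_rows),
                               pd.DataFrame(stat_rows).reset_index(drop=True),
                               dict(meta))
        chunk_writer(chunk)
        labels, param_rows, stat_rows = [], [], []

    for mid, spec in specs.items():
        sample = sample_configs[mid]
        for _ in range(n_per_model):
            params = draw_params(spec, rng)
            data = simulate_dataset(mid, params, sample, rng)
            vec = microsat_sumstats(data, grouping=grouping)
            labels.append(mid)
            param_rows.append(params.as_dict())
            stat_rows.append(vec)
            if chunk_writer is not None and len(labels) >= chunk_size:
                flush()
    if chunk_writer is not None:
        flush()
        return None
    return ReferenceTable(np.array(labels), pd.DataFrame(param_rows),
                          pd.DataFrame(stat_rows).reset_index(drop=True), meta)


def posterior_summaries(post: ParameterPosterior) -> pd.DataFrame:
    """Per-parameter (5%, mean, median, mode, 95% HPD) on the linear scale."""
    rows = {}
    w = post.weights
    for name in post.samples.columns:
        x = post.samples[name].to_numpy(float)
        lo, hi = hpd_interval(x, w, 0.95)
        rows[name] = {
            "q5": weighted_quantile(x, w, 0.05),
            "mean": float(np.average(x, weights=w)),
            "median": weighted_quantile(x, w, 0.5),
            "mode": weighted_mode(x, w),
            "hpd_low": lo,
            "hpd_high": hi,
        }
    return pd.DataFrame(rows).T[
        ["q5", "mean", "median", "mode", "hpd_low", "hpd_high"]]
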