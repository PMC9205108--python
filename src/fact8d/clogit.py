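"""QALY-parameterized conditional logit for paired DCE choices.

The deterministic utility of alternative j in choice set s for respondent
i is ``V_isj = alpha * t_isj + sum_dl beta_dl * x_isjdl * t_isj``: every
dimension-level dummy enters multiplied by survival duration, so a state
lived for zero years has zero utility and the implied time trade-off is
proportionally constant.  With i.i.d. Gumbel errors the probability of
choosing A over B is ``logistic(V_A - V_B)``, i.e. a binary logit on
differenced regressors with no intercept.

Estimation is Newton–Raphson maximum (pseudo-)likelihood with analytic
gradient and Hessian, converged at gradient max-norm < 1e-6.  Respondent
survey weights multiply each respondent's log-likelihood contribution
(pseudo-ML); the covariance is always the cluster-robust sandwich with
clusters = respondents, which collapses to the heteroskedasticity-robust
(HC0) form when every cluster holds a single observation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve as scipy_cho_solve
from scipy.special import expit, log_expit

from .descriptive import DIMENSIONS, N_LEVELS
from .weights import WeightVector

GRADIENT_TOL = 1e-6

LEVELS_TO_ESTIMATE = tuple(range(2, N_LEVELS + 1))  # level 1 is the reference


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class LevelGroup:
    """A contiguous run of severity levels sharing one coefficient.

    ``to_reference`` pins the group's coefficient at 0 (merged into the
    no-problems reference level).
    """

    levels: tuple[int, ...]
    to_reference: bool = False

    def __post_init__(self) -> None:
        lv = tuple(int(l) for l in self.levels)
        if not lv or list(lv) != list(range(lv[0], lv[-1] + 1)):
            raise ValueError(f"level group must be a contiguous ascending run, got {lv}")
        if not all(2 <= l <= N_LEVELS for l in lv):
            raise ValueError(f"estimable levels are 2..{N_LEVELS}, got {lv}")
        object.__setattr__(self, "levels", lv)

    @property
    def label(self) -> str:
        if len(self.levels) == 1:
            return f"L{self.levels[0]}"
        return f"L{self.levels[0]}-{self.levels[-1]}"


@dataclass(frozen=True)
class ModelSpec:
    """Per-dimension partition of levels 2..5 into coefficient groups."""

    dimensions: dict[str, tuple[LevelGroup, ...]]

    def __post_init__(self) -> None:
        clean = {}
        for dim in DIMENSIONS:
            groups = tuple(self.dimensions.get(dim, ()))
            covered = [l for g in groups for l in g.levels]
            if covered != list(LEVELS_TO_ESTIMATE):
                raise ValueError(
                    f"{dim}: groups must partition levels {LEVELS_TO_ESTIMATE} "
                    f"in order, got {covered}"
                )
            clean[dim] = groups
        object.__setattr__(self, "dimensions", clean)

    @classmethod
    def full(cls) -> "ModelSpec":
        """One coefficient per level 2..5 of every dimension (33 parameters)."""
        return cls({d: tuple(LevelGroup((l,)) for l in LEVELS_TO_ESTIMATE)
                    for d in DIMENSIONS})

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelSpec":
        """Build from {dim: {"reference": [[levels]], "groups": [[levels]]}}.

        Groups are re-sorted by their mildest level so reference and
        estimated runs interleave correctly.
        """
        dims = {}
        for dim, spec in payload.items():
            groups = [LevelGroup(tuple(g), to_reference=True)
                      for g in spec.get("reference", [])]
            groups += [LevelGroup(tuple(g)) for g in spec.get("groups", [])]
            dims[dim] = tuple(sorted(groups, key=lambda g: g.levels[0]))
        return cls(dims)

    # -- bookkeeping ---------------------------------------------------

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = ["duration"]
        for dim in DIMENSIONS:
            names += [f"{dim}:{g.label}" for g in self.dimensions[dim]
                      if not g.to_reference]
        return tuple(names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def level_column(self) -> dict[str, np.ndarray]:
        """Per dimension: length-5 array mapping level -> column index (-1 = none)."""
        out = {}
        col = 1  # column 0 is duration
        for dim in DIMENSIONS:
            mapping = np.full(N_LEVELS, -1, dtype=int)
            for g in self.dimensions[dim]:
                if g.to_reference:
                    continue
                for l in g.levels:
                    mapping[l - 1] = col
                col += 1
            out[dim] = mapping
        return out

    def expand(self, params: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        """Expand a parameter vector to (alpha, per-level beta arrays)."""
        cols = self.level_column()
        alpha = float(params[0])
        beta = {}
        for dim in DIMENSIONS:
            b = np.zeros(N_LEVELS)
            for l in range(2, N_LEVELS + 1):
                c = cols[dim][l - 1]
                if c >= 0:
                    b[l - 1] = params[c]
            beta[dim] = b
        return alpha, beta

    # -- merges (used by the monotonicity-constraint loop) --------------

    def merge_group_to_reference(self, dim: str, group_index: int) -> "ModelSpec":
        groups = list(self.dimensions[dim])
        g = groups[group_index]
        if any(not h.to_reference for h in groups[:group_index]):
            raise ValueError(
                f"{dim} {g.label}: only a group adjacent to the reference "
                "(all milder levels already reference) can merge into it"
            )
        groups[group_index] = LevelGroup(g.levels, to_reference=True)
        return ModelSpec({**self.dimensions, dim: tuple(groups)})

    def merge_adjacent(self, dim: str, group_index: int) -> "ModelSpec":
        """Merge group ``group_index`` with the next (more severe) group."""
        groups = list(self.dimensions[dim])
        a, b = groups[group_index], groups[group_index + 1]
        if a.to_reference or b.to_reference:
            raise ValueError("cannot pair-merge with a reference group")
        merged = LevelGroup(a.levels + b.levels)
        groups[group_index:group_index + 2] = [merged]
        return ModelSpec({**self.dimensions, dim: tuple(groups)})


# ---------------------------------------------------------------------------
# data preparation


def build_regressors(dataset: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-alternative regressor rows under the duration-interaction coding.

    Row j carries duration ``t_j`` in the duration column and ``t_j`` in the
    column of each active (dimension, level-group) dummy; reference levels
    contribute nothing.
    """
    n = len(dataset)
    k = spec.n_parameters
    X = np.zeros((n, k))
    t = dataset["duration"].to_numpy(float)
    if not np.isfinite(t).all():
        raise ValueError("non-finite durations in dataset")
    X[:, 0] = t
    cols = spec.level_column()
    for dim in DIMENSIONS:
        levels = dataset[dim].to_numpy()
        if not np.isin(levels, np.arange(1, N_LEVELS + 1)).all():
            bad = sorted(set(levels) - set(range(1, N_LEVELS + 1)))
            raise ValueError(f"{dim}: unseen levels {bad}")
        mapping = cols[dim]
        for l in range(2, N_LEVELS + 1):
            c = mapping[l - 1]
            if c >= 0:
                X[levels == l, c] += t[levels == l]
    return X, spec.parameter_names


@dataclass(frozen=True)
class _PairedData:
    """Differenced design: one row per choice-set observation (A minus B)."""

    dx: np.ndarray        # (M, k) regressor differences X_A - X_B
    y: np.ndarray         # (M,) 1 if A chosen
    w: np.ndarray         # (M,) respondent weight
    clusters: np.ndarray  # (M,) respondent codes 0..C-1
    n_clusters: int
    fingerprint: str


def _fingerprint(dataset: pd.DataFrame, weights: np.ndarray) -> str:
    cols = ["respondent", "set", "alt", "chosen", "duration", *DIMENSIONS]
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(dataset[cols], index=False).to_numpy().tobytes())
    h.update(np.asarray(weights, float).tobytes())
    return h.hexdigest()[:16]


def pair_dataset(dataset: pd.DataFrame, spec: ModelSpec,
                 weights: WeightVector | None = None) -> _PairedData:
    df = dataset.sort_values(["respondent", "set", "alt"], kind="stable")
    alt = df["alt"].to_numpy()
    if len(df) % 2 or not (np.all(alt[0::2] == "A") and np.all(alt[1::2] == "B")):
        raise ValueError("dataset must hold exactly one A and one B row per set")
    X, _ = build_regressors(df, spec)
    dx = X[0::2] - X[1::2]
    chosen = df["chosen"].to_numpy()
    if not np.array_equal(chosen[0::2] + chosen[1::2], np.ones(len(df) // 2, dtype=chosen.dtype)):
        raise ValueError("exactly one alternative must be chosen in each set")
    y = chosen[0::2].astype(float)
    resp = df["respondent"].to_numpy()[0::2]
    codes, _ = pd.factorize(resp)
    if weights is None:
        w = np.ones(len(y))
    else:
        w = weights.as_series().reindex(resp).to_numpy()
        if np.isnan(w).any():
            raise ValueError("weights are missing for some respondents in the dataset")
    return _PairedData(dx=dx, y=y, w=w, clusters=codes,
                       n_clusters=int(codes.max()) + 1,
                       fingerprint=_fingerprint(df, w))


# ---------------------------------------------------------------------------
# likelihood


def _ll_grad_hess(params: np.ndarray, data: _PairedData,
                  hessian: bool = True) -> tuple[float, np.ndarray, np.ndarray | None]:
    z = data.dx @ params
    # log P(chosen) = y*log sigma(z) + (1-y)*log sigma(-z), numerically stable
    ll = float(np.sum(data.w * (data.y * log_expit(z) + (1 - data.y) * log_expit(-z))))
    p = expit(z)
    resid = data.w * (data.y - p)
    grad = data.dx.T @ resid
    H = None
    if hessian:
        wpq = data.w * p * (1 - p)
        H = -(data.dx * wpq[:, None]).T @ data.dx
    return ll, grad, H


def loglik(params: np.ndarray, dataset: pd.DataFrame, spec: ModelSpec,
           weights: WeightVector | None = None) -> tuple[float, np.ndarray]:
    """Weighted conditional-logit log-likelihood and its analytic gradient."""
    params = np.asarray(params, float)
    data = pair_dataset(dataset, spec, weights)
    if params.shape != (spec.n_parameters,):
        raise ValueError(
            f"expected {spec.n_parameters} parameters, got shape {params.shape}"
        )
    ll, grad, _ = _ll_grad_hess(params, data, hessian=False)
    return ll, grad


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    params: np.ndarray
    names: tuple[str, ...]
    cov: np.ndarray
    loglik: float
    n_parameters: int
    n_obs: int           # choice-set observations (the BIC sample size)
    n_clusters: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    grad_norm: float
    weighted: bool
    fingerprint: str

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def alpha(self) -> float:
        return float(self.params[0])

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.params)))

    def beta_by_level(self) -> dict[str, np.ndarray]:
        return self.spec.expand(self.params)[1]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "robust_se": self.se},
                            index=pd.Index(self.names, name="parameter"))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients(),
            "robust_se": dict(zip(self.names, map(float, self.se))),
            "covariance": self.cov.tolist(),
            "log_likelihood": self.loglik,
            "n_parameters": self.n_parameters,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "gradient_max_norm": self.grad_norm,
            "weighted": self.weighted,
            "fingerprint": self.fingerprint,
        }


def _cho_solve(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    return scipy_cho_solve((chol, True), b)


def information_criteria(loglik_value: float, k: int, n_obs: int) -> tuple[float, float]:
    """AIC = 2k - 2LL; BIC = k ln(M) - 2LL with M choice-set observations."""
    aic = 2 * k - 2 * loglik_value
    bic = k * float(np.log(n_obs)) - 2 * loglik_value
    return aic, bic


def fit(dataset: pd.DataFrame, spec: ModelSpec | None = None,
        weights: WeightVector | None = None, *,
        max_iter: int = 100, tol: float = GRADIENT_TOL) -> FitResult:
    """Maximum (pseudo-)likelihood fit with cluster-robust sandwich covariance.

    Newton–Raphson from a zero start with step-halving; converged when the
    gradient max-norm drops below ``tol``.  The sandwich covariance sums
    score contributions within respondents, so the repeated choices of one
    person never masquerade as independent information.
    """
    spec = spec or ModelSpec.full()
    data = pair_dataset(dataset, spec, weights)
    if data.y.min() == data.y.max():
        raise FitError("degenerate dataset: the same alternative is chosen everywhere")
    k = spec.n_parameters
    params = np.zeros(k)
    ll, grad, H = _ll_grad_hess(params, data)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            # Cholesky of the information matrix doubles as the positive-
            # definiteness check: 16 choice sets cannot identify 33
            # parameters, so a too-small design fails here, not downstream
            chol = np.linalg.cholesky(-H)
            step = _cho_solve(chol, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                f"singular Hessian at iteration {it}: separation, collinear "
                "regressors, or too few distinct choice sets for the "
                "parameter count"
            ) from exc
        # step-halving keeps the ascent monotone far from the optimum
        scale = 1.0
        for _ in range(30):
            new_params = params + scale * step
            new_ll, new_grad, new_H = _ll_grad_hess(new_params, data)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            scale /= 2
        else:
            raise FitError(f"line search failed at iteration {it}")
        params, ll, grad, H = new_params, new_ll, new_grad, new_H
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    if not converged:
        raise FitError(
            f"no convergence in {max_iter} iterations "
            f"(gradient max-norm {np.max(np.abs(grad)):.2e})"
        )

    # cluster-robust sandwich: bread = inverse information, meat = summed
    # within-respondent scores (no small-sample factor, so singleton
    # clusters reproduce HC0 exactly)
    z = data.dx @ params
    scores = data.dx * (data.w * (data.y - expit(z)))[:, None]
    G = np.zeros((data.n_clusters, k))
    np.add.at(G, data.clusters, scores)
    chol = np.linalg.cholesky(-H)
    bread = _cho_solve(chol, np.eye(k))
    cov = bread @ (G.T @ G) @ bread
    cov = (cov + cov.T) / 2

    n_obs = len(data.y)
    aic, bic = information_criteria(ll, k, n_obs)
    return FitResult(
        spec=spec, params=params, names=spec.parameter_names, cov=cov,
        loglik=ll, n_parameters=k, n_obs=n_obs, n_clusters=data.n_clusters,
        aic=aic, bic=bic, converged=converged, n_iter=it,
        grad_norm=float(np.max(np.abs(grad))),
        weighted=weights is not None, fingerprint=data.fingerprint,
    )


def lr_test(nested: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one.

    Both fits must come from the same dataset and weights (checked via a
    data fingerprint).  The statistic is floored at 0: a constrained model
    can never beat the model it is nested in, but finite optimizer
    tolerance can produce a tiny negative difference.
    """
    if nested.fingerprint != full.fingerprint:
        raise ValueError("fits come from different datasets/weights "
                         f"({nested.fingerprint} vs {full.fingerprint})")
    if nested.n_parameters >= full.n_parameters:
        raise ValueError("the nested model must have fewer parameters")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    df = full.n_parameters - nested.n_parameters
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return stat, df, p
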