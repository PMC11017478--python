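"""Partition among-population phenotypic variance into environmental,
genetic-structure, and residual among-population components.

The model is a random-regression mixed model for an individual phenotype
``z_ij`` (a shape PC score of individual ``i`` in population ``j``):

fixed part
    ``E[z]_ij = alpha + beta_L L_i + beta_T T_j + beta_O O_j + beta_D D_j
    + delta_T T_j L_i + delta_O O_j L_i + delta_D D_j L_i``
    with ``L`` individual fork length and ``T, O, D`` population-level
    covariates (temperature, openings, distance to the source lake), all
    mean-centred and scaled to unit variance before fitting.

random part
    ``z_ij = E[z]_ij + g_a,j + g_b,j L_i + c_a,j + c_b,j L_i + e_ij``
    where the ``g`` effects (intercepts/slopes) are drawn jointly across
    populations with covariance proportional to a genetic similarity matrix
    ``S`` derived from chord distances, the ``c`` effects are independent
    across populations, and ``e`` is the individual residual.

Estimation is by restricted maximum likelihood (REML) on log-parameterized
variance components, with the Woodbury identity exploiting the
low-dimensional random-effect structure.  The partition follows the
fixed-effect-variance recovery of de Villemereuil et al.: the environmental
variance is the quadratic form ``beta' E_E beta`` over the population-level
covariate covariance, and the among-population total
``sigma_t^2 = var_env + var_gen + var_cave`` is split into proportions
E, G and O.  Random slopes are estimated but excluded from the partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import block_diag
from skbio import DistanceMatrix

__all__ = [
    "SimilarityMatrix",
    "MixedModelFit",
    "VariancePartition",
    "similarity_from_distance",
    "fit_mixed_model",
    "env_variance",
    "partition_variance",
    "partition_uncertainty",
    "run_partition_suite",
]

ENV_COLUMNS = ("temperature", "openings", "distance")


@dataclass
class SimilarityMatrix:
    """Population similarity ``S`` (symmetric, PSD, unit diagonal) with provenance."""

    values: np.ndarray
    labels: list[str]
    method: str
    min_eigenvalue_before_repair: float
    repaired: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def similarity_from_distance(dce: DistanceMatrix, method: str = "linear",
                             length_scale: float | None = None) -> SimilarityMatrix:
    """Map a genetic distance matrix to a similarity matrix for the mixed model.

    ``method='linear'`` (default): ``S = 1 - D / max(D)``.
    ``method='exponential'``: ``S = exp(-D / length_scale)`` with
    ``length_scale`` defaulting to the mean off-diagonal distance.
    Either way the result is repaired to positive semi-definiteness
    (eigenvalues below 0 raised to 1e-8) and rescaled to unit diagonal; the
    pre-repair minimum eigenvalue is recorded.
    """
    d = np.array(dce.data, dtype=float)
    dmax = d.max()
    if dmax == 0:
        warnings.warn("all distances are 0: populations indistinguishable, S = 1")
        s = np.ones_like(d)
    elif method == "linear":
        s = 1.0 - d / dmax
    elif method == "exponential":
        scale = length_scale if length_scale is not None else d[np.triu_indices_from(d, 1)].mean()
        s = np.exp(-d / scale)
    else:
        raise ValueError(f"unknown method {method!r}")
    s = (s + s.T) / 2
    w, v = np.linalg.eigh(s)
    min_eig = float(w.min())
    repaired = min_eig < -1e-12
    if repaired:
        w = np.maximum(w, 1e-8)
        s = (v * w) @ v.T
        scale = np.sqrt(np.diag(s))
        s = s / np.outer(scale, scale)
        s = (s + s.T) / 2
    return SimilarityMatrix(values=s, labels=[str(i) for i in dce.ids], method=method,
                            min_eigenvalue_before_repair=min_eig, repaired=repaired)


@dataclass
class MixedModelFit:
    """REML fit of the random-regression mixed model."""

    fixed_effects: pd.Series
    var_gen: float
    var_gen_slope: float
    var_cave: float
    var_cave_slope: float
    var_resid: float
    reml_loglik: float
    converged: bool
    n_individuals: int
    populations: list[str]
    message: str = ""
    # internals retained for simulation/bootstrap
    _design: dict = field(default_factory=dict, repr=False)

    @property
    def variance_components(self) -> pd.Series:
        return pd.Series({
            "var_gen": self.var_gen,
            "var_gen_slope": self.var_gen_slope,
            "var_cave": self.var_cave,
            "var_cave_slope": self.var_cave_slope,
            "var_resid": self.var_resid,
        })


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn(f"covariate {name} is constant; left centred at 0")
        return x - x.mean()
    return (x - x.mean()) / sd


def _build_design(data: pd.DataFrame, env: pd.DataFrame, response: str,
                  include_slopes: bool, include_cave: bool):
    """Assemble y, fixed design X, random design U and block structure."""
    pops = [str(p) for p in env.index]
    pop_of = data["population"].astype(str).to_numpy()
    unknown = set(pop_of) - set(pops)
    if unknown:
        raise ValueError(f"individuals from populations absent in env table: {sorted(unknown)}")
    y = data[response].to_numpy(dtype=float)
    n = y.size
    L = _standardize(data["fork_length"].to_numpy(dtype=float), "fork_length")
    env_std = {}
    for c in ENV_COLUMNS:
        env_std[c] = _standardize(env[c].to_numpy(dtype=float), c)
    pop_index = {p: k for k, p in enumerate(pops)}
    j = np.array([pop_index[p] for p in pop_of])
    T, O, Dv = (env_std[c][j] for c in ENV_COLUMNS)
    X = np.column_stack([
        np.ones(n), L, T, O, Dv, T * L, O * L, Dv * L,
    ])
    x_names = ["alpha", "beta_L", "beta_T", "beta_O", "beta_D",
               "delta_T", "delta_O", "delta_D"]
    Z = np.zeros((n, len(pops)))
    Z[np.arange(n), j] = 1.0
    Zl = Z * L[:, None]
    blocks = [("var_gen", Z, "S"), ]
    if include_slopes:
        blocks.append(("var_gen_slope", Zl, "S"))
    if include_cave:
        blocks.append(("var_cave", Z, "I"))
        if include_slopes:
            blocks.append(("var_cave_slope", Zl, "I"))
    env_matrix = np.column_stack([env_std[c] for c in ENV_COLUMNS])
    return {
        "y": y, "X": X, "x_names": x_names, "blocks": blocks, "pops": pops,
        "env_std": env_matrix, "L": L, "j": j, "Z": Z, "Zl": Zl,
    }


class _REMLProblem:
    """Profiled-free REML objective using the Woodbury identity.

    V = sum_k sigma_k^2 U_k G_k U_k' + sigma_e^2 I, with each G_k either S or
    I over populations.  All heavy cross-products are precomputed once.
    """

    def __init__(self, y, X, blocks, S):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.names = [b[0] for b in blocks]
        us = [b[1] for b in blocks]
        self.U = np.hstack(us) if us else np.zeros((self.n, 0))
        # square roots of the per-block population covariance
        w, v = np.linalg.eigh((S + S.T) / 2)
        w = np.maximum(w, 0.0)
        s_half = (v * np.sqrt(w)) @ v.T
        npop = S.shape[0]
        halves = []
        for _, _, kind in blocks:
            halves.append(s_half if kind == "S" else np.eye(npop))
        self.halves = halves
        self.block_sizes = [u.shape[1] for u in us]
        self.UtU = self.U.T @ self.U
        self.UtX = self.U.T @ X
        self.Uty = self.U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _gamma_half(self, sigmas):
        mats = [np.sqrt(s2) * h for s2, h in zip(sigmas, self.halves)]
        return block_diag(*mats) if mats else np.zeros((0, 0))

    def neg2_reml(self, log_params):
        sigmas = np.exp(log_params[:-1])
        sig_e = np.exp(log_params[-1])
        q = self.UtU.shape[0]
        gh = self._gamma_half(sigmas)
        M = np.eye(q) + (gh @ self.UtU @ gh) / sig_e
        try:
            cm = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return 1e12
        logdet_v = self.n * np.log(sig_e) + 2.0 * np.sum(np.log(np.diag(cm)))
        ghUtX = gh @ self.UtX
        ghUty = gh @ self.Uty
        sol_x = np.linalg.solve(cm, ghUtX)
        sol_x = np.linalg.solve(cm.T, sol_x)
        sol_y = np.linalg.solve(cm, ghUty)
        sol_y = np.linalg.solve(cm.T, sol_y)
        XtVinvX = (self.XtX - (ghUtX.T @ sol_x) / sig_e) / sig_e
        XtVinvy = (self.Xty - (ghUtX.T @ sol_y) / sig_e) / sig_e
        ytVinvy = (self.yty - (ghUty @ sol_y) / sig_e) / sig_e
        try:
            cx = np.linalg.cholesky((XtVinvX + XtVinvX.T) / 2)
        except np.linalg.LinAlgError:
            return 1e12
        beta = np.linalg.solve(cx.T, np.linalg.solve(cx, XtVinvy))
        logdet_xvx = 2.0 * np.sum(np.log(np.diag(cx)))
        quad = ytVinvy - float(beta @ XtVinvy)
        return logdet_v + logdet_xvx + quad

    def gls(self, sigmas, sig_e):
        log_params = np.log(np.r_[np.maximum(sigmas, 1e-300), max(sig_e, 1e-300)])
        # recompute beta at the optimum
        q = self.UtU.shape[0]
        gh = self._gamma_half(np.exp(log_params[:-1]))
        M = np.eye(q) + (gh @ self.UtU @ gh) / sig_e
        cm = np.linalg.cholesky(M)
        ghUtX = gh @ self.UtX
        ghUty = gh @ self.Uty
        sol_x = np.linalg.solve(cm.T, np.linalg.solve(cm, ghUtX))
        sol_y = np.linalg.solve(cm.T, np.linalg.solve(cm, ghUty))
        XtVinvX = (self.XtX - (ghUtX.T @ sol_x) / sig_e) / sig_e
        XtVinvy = (self.Xty - (ghUtX.T @ sol_y) / sig_e) / sig_e
        beta = np.linalg.solve((XtVinvX + XtVinvX.T) / 2, XtVinvy)
        return beta


def fit_mixed_model(data: pd.DataFrame, env: pd.DataFrame, similarity: SimilarityMatrix,
                    response: str, include_slopes: bool = True,
                    include_cave: bool = True, n_starts: int = 4,
                    seed: int | None = None) -> MixedModelFit:
    """Fit the random-regression mixed model by REML.

    Parameters
    ----------
    data
        Individual table with columns ``response``, ``fork_length``,
        ``population``.
    env
        Population-level covariates (``temperature``, ``openings``,
        ``distance``), indexed by population; must match ``similarity``.
    similarity
        Output of :func:`similarity_from_distance`; its label order defines
        the population order.
    include_slopes, include_cave
        Switch off the random slopes and/or the genetics-independent cave
        intercepts (used e.g. to reduce to a textbook random-intercept
        model).
    """
    if data["population"].nunique() < 3:
        raise ValueError("need at least 3 populations")
    if len(data) < 2 * data["population"].nunique():
        warnings.warn("fewer than 2 individuals per population on average")
    env = env.loc[[l for l in similarity.labels]]
    S = similarity.values
    if include_cave and np.allclose(S, np.eye(S.shape[0])):
        warnings.warn(
            "S is the identity: var_gen and var_cave are not separately "
            "identifiable (only their sum is)"
        )
    design = _build_design(data, env, response, include_slopes, include_cave)
    problem = _REMLProblem(design["y"], design["X"], design["blocks"], S)
    var_y = design["y"].var(ddof=1)
    if var_y == 0:
        raise ValueError("response has zero variance")
    k = len(design["blocks"])
    rng = np.random.default_rng(seed)
    starts = [np.log(np.r_[np.full(k, var_y / (k + 1)), var_y / 2])]
    starts.append(np.log(np.r_[np.full(k, var_y / 50), var_y]))
    for _ in range(max(n_starts - 2, 0)):
        starts.append(np.log(var_y) + rng.uniform(-4, 1, size=k + 1))
    best = None
    for x0 in starts:
        res = optimize.minimize(problem.neg2_reml, x0, method="L-BFGS-B",
                                bounds=[(-30.0, 10.0 + np.log(max(var_y, 1e-12)))] * (k + 1),
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("REML optimization failed from all starts")
    converged = bool(best.success) or best.fun < 1e12
    sigmas = np.exp(best.x[:-1])
    sig_e = float(np.exp(best.x[-1]))
    beta = problem.gls(sigmas, sig_e)
    comps = dict.fromkeys(
        ["var_gen", "var_gen_slope", "var_cave", "var_cave_slope"], 0.0)
    for name, s2 in zip(problem.names, sigmas):
        comps[name] = float(s2)
    fit = MixedModelFit(
        fixed_effects=pd.Series(beta, index=design["x_names"]),
        var_gen=comps["var_gen"],
        var_gen_slope=comps["var_gen_slope"],
        var_cave=comps["var_cave"],
        var_cave_slope=comps["var_cave_slope"],
        var_resid=sig_e,
        reml_loglik=-0.5 * float(best.fun),
        converged=converged,
        n_individuals=len(data),
        populations=design["pops"],
        message=str(best.message),
    )
    fit._design = {**design, "S": S, "include_slopes": include_slopes,
                   "include_cave": include_cave, "response": response,
                   "similarity": similarity, "env": env, "data": data}
    return fit


def env_variance(beta, env_std: np.ndarray) -> float:
    """Phenotypic variance attributable to the environmental fixed effects.

    ``var_env = beta' E_E beta`` where ``E_E`` is the covariance matrix of
    the standardized population-level covariates with every population
    weighted equally.
    """
    beta = np.asarray(beta, dtype=float)
    env_std = np.asarray(env_std, dtype=float)
    if env_std.ndim != 2 or env_std.shape[1] != beta.size:
        raise ValueError("beta length must match the environmental covariate count")
    cov = np.cov(env_std, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return float(beta @ cov @ beta)


@dataclass
class VariancePartition:
    """E/G/O proportions of among-population variance with repeatabilities."""

    response: str
    var_env: float
    var_gen: float
    var_cave: float
    var_resid: float
    sigma_t: float
    sigma_T: float
    E: float
    G: float
    O: float
    repeatability_total: float
    repeatability_conditional: float
    intervals: pd.DataFrame | None = None

    def as_series(self) -> pd.Series:
        return pd.Series({
            "var_env": self.var_env, "var_gen": self.var_gen,
            "var_cave": self.var_cave, "var_resid": self.var_resid,
            "sigma_t": self.sigma_t, "sigma_T": self.sigma_T,
            "E": self.E, "G": self.G, "O": self.O,
            "repeatability_total": self.repeatability_total,
            "repeatability_conditional": self.repeatability_conditional,
        }, name=self.response)


def partition_variance(fit: MixedModelFit, env: pd.DataFrame | None = None) -> VariancePartition:
    """Partition the among-population variance of a fitted model.

    ``E = var_env / sigma_t``, ``G = var_gen / sigma_t``,
    ``O = var_cave / sigma_t`` with ``sigma_t = var_env + var_gen +
    var_cave`` (random slopes excluded).  Repeatabilities are ``sigma_t /
    sigma_T`` and ``(var_gen + var_cave) / sigma_T`` with
    ``sigma_T = sigma_t + var_resid``.
    """
    if not fit.converged:
        raise ValueError("cannot partition a non-converged fit")
    if env is not None:
        env_std = np.column_stack([
            _standardize(env[c].to_numpy(dtype=float), c) for c in ENV_COLUMNS
        ])
    else:
        env_std = fit._design["env_std"]
    beta_env = fit.fixed_effects[["beta_T", "beta_O", "beta_D"]].to_numpy()
    var_env = env_variance(beta_env, env_std)
    sigma_t = var_env + fit.var_gen + fit.var_cave
    sigma_T = sigma_t + fit.var_resid
    if sigma_t == 0:
        raise ValueError("sigma_t is 0: proportions undefined")
    return VariancePartition(
        response=fit._design.get("response", "response"),
        var_env=var_env, var_gen=fit.var_gen, var_cave=fit.var_cave,
        var_resid=fit.var_resid, sigma_t=sigma_t, sigma_T=sigma_T,
        E=var_env / sigma_t, G=fit.var_gen / sigma_t, O=fit.var_cave / sigma_t,
        repeatability_total=sigma_t / sigma_T,
        repeatability_conditional=(fit.var_gen + fit.var_cave) / sigma_T,
    )


def simulate_response(fit: MixedModelFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a response vector from the fitted model (parametric bootstrap)."""
    d = fit._design
    X, Z, Zl, S = d["X"], d["Z"], d["Zl"], d["S"]
    npop = Z.shape[1]
    mean = X @ fit.fixed_effects.to_numpy()
    w, v = np.linalg.eigh(S)
    s_half = (v * np.sqrt(np.maximum(w, 0))) @ v.T
    y = mean.copy()
    if fit.var_gen > 0:
        y += Z @ (s_half @ rng.standard_normal(npop)) * np.sqrt(fit.var_gen)
    if fit.var_gen_slope > 0:
        y += Zl @ (s_half @ rng.standard_normal(npop)) * np.sqrt(fit.var_gen_slope)
    if fit.var_cave > 0:
        y += Z @ rng.standard_normal(npop) * np.sqrt(fit.var_cave)
    if fit.var_cave_slope > 0:
        y += Zl @ rng.standard_normal(npop) * np.sqrt(fit.var_cave_slope)
    y += rng.standard_normal(y.size) * np.sqrt(fit.var_resid)
    return y


def partition_uncertainty(fit: MixedModelFit, n_boot: int = 200,
                          seed: int | None = None, ci: float = 0.95,
                          max_failure_rate: float = 0.2) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for the partition quantities.

    Responses are simulated from the fitted model, the model refit and the
    partition recomputed; more than ``max_failure_rate`` non-convergence is
    an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    d = fit._design
    rows = []
    failures = 0
    for _ in range(n_boot):
        y = simulate_response(fit, rng)
        data = d["data"].copy()
        data = data.assign(**{d["response"]: y})
        try:
            refit = fit_mixed_model(
                data, d["env"], d["similarity"], d["response"],
                include_slopes=d["include_slopes"], include_cave=d["include_cave"],
                n_starts=2, seed=int(rng.integers(2**31)),
            )
            rows.append(partition_variance(refit).as_series())
        except (RuntimeError, ValueError):
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    boot = pd.DataFrame(rows)
    alpha = (1 - ci) / 2
    point = partition_variance(fit).as_series()
    out = pd.DataFrame({
        "estimate": point,
        "ci_low": boot.quantile(alpha),
        "ci_high": boot.quantile(1 - alpha),
    })
    out.attrs["n_boot"] = n_boot - failures
    out.attrs["failures"] = failures
    return out


def run_partition_suite(scores: pd.DataFrame, dce: DistanceMatrix, env: pd.DataFrame,
                        traits, exclude=(), n_boot: int = 0,
                        seed: int | None = None, **fit_kwargs) -> pd.DataFrame:
    """One variance partition per selected trait column.

    ``scores`` must carry ``population`` and ``fork_length`` columns plus the
    trait score columns.  ``exclude`` removes artifact axes (e.g. bending
    PCs) from the requested list.  Returns one row per retained trait.
    """
    traits = [t for t in traits if t not in set(exclude)]
    if not traits:
        raise ValueError("no traits selected")
    missing = [t for t in traits if t not in scores.columns]
    if missing:
        raise KeyError(f"traits absent from scores table: {missing}")
    sim = similarity_from_distance(dce)
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        fit = fit_mixed_model(scores, env, sim, trait,
                              seed=int(rng.integers(2**31)), **fit_kwargs)
        part = partition_variance(fit)
        row = part.as_series()
        if n_boot:
            intervals = partition_uncertainty(fit, n_boot=n_boot,
                                              seed=int(rng.integers(2**31)))
            for q in ("E", "G", "O"):
                row[f"{q}_ci_low"] = intervals.loc[q, "ci_low"]
                row[f"{q}_ci_high"] = intervals.loc[q, "ci_high"]
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(traits, name="trait"))
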