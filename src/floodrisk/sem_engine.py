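"""Maximum-likelihood covariance-structure (SEM) engine.

Implements the four-latent measurement + structural model for the flood
survey: 28 items loading on severity / preparedness / help / php, with
structural paths severity->php, preparedness->php, help->php and
preparedness->help, and a free severity<->preparedness exogenous covariance.

The model-implied covariance follows the standard latent-path algebra

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

with unit-variance identification for the latents (exogenous variances fixed
to 1, endogenous residual variances free).  Estimation minimizes the
normal-theory ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with an analytic gradient; chi^2 = (n - 1) F_ML at the minimum.  Fit indices
(chi^2/df, RMSEA, CFI against the independence baseline), the standardized
solution, direct/indirect/total effect decomposition and squared multiple
correlations are derived from the fitted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .synthetic_data import LATENTS, DEFAULT_N_ITEMS, GeneratorConfig, item_names

__all__ = [
    "SemModelSpec",
    "SemParams",
    "SemFit",
    "FitIndices",
    "EffectTable",
    "StandardizedSolution",
    "build_default_spec",
    "implied_covariance",
    "fit_ml",
    "fit_indices",
    "fit_indices_from_stats",
    "standardized_solution",
    "effect_decomposition",
    "effects_from_paths",
    "squared_multiple_correlations",
    "params_from_generator_config",
]


@dataclass(frozen=True)
class SemModelSpec:
    """Topology of a latent measurement + structural model.

    ``indicators`` maps each observed item to the single latent it measures
    (order defines the row order of Sigma).  ``structural_edges`` are directed
    (source, target) latent paths; ``exogenous_covariances`` are free latent
    covariances among exogenous latents.  Identification is unit-variance:
    exogenous latent variances fixed at 1, endogenous residual variances free.
    """

    latents: tuple[str, ...]
    indicators: tuple[tuple[str, str], ...]  # (item, latent) in row order
    structural_edges: tuple[tuple[str, str], ...]  # (source, target)
    exogenous_covariances: tuple[tuple[str, str], ...] = ()
    correlated_errors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        known = set(self.latents)
        for item, lat in self.indicators:
            if lat not in known:
                raise ValueError(f"indicator {item} loads on unknown latent {lat}")
        items = [it for it, _ in self.indicators]
        if len(set(items)) != len(items):
            raise ValueError("each indicator may appear once (loads on exactly one latent)")
        for s, t in self.structural_edges:
            if s not in known or t not in known:
                raise ValueError(f"structural edge {s}->{t} uses unknown latent")
        if self._has_cycle():
            raise ValueError("structural graph must be acyclic")
        if self.df < 0:
            raise ValueError("model is not identified: negative degrees of freedom")

    def _has_cycle(self) -> bool:
        adj: dict[str, list[str]] = {l: [] for l in self.latents}
        for s, t in self.structural_edges:
            adj[s].append(t)
        state: dict[str, int] = {}

        def visit(u: str) -> bool:
            state[u] = 1
            for v in adj[u]:
                if state.get(v) == 1 or (state.get(v) is None and visit(v)):
                    return True
            state[u] = 2
            return False

        return any(state.get(l) is None and visit(l) for l in self.latents)

    @property
    def item_order(self) -> tuple[str, ...]:
        return tuple(it for it, _ in self.indicators)

    @property
    def n_observed(self) -> int:
        return len(self.indicators)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.structural_edges}
        return tuple(l for l in self.latents if l in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.structural_edges}
        return tuple(l for l in self.latents if l not in targets)

    @property
    def n_free_parameters(self) -> int:
        return (
            len(self.indicators)
            + len(self.structural_edges)
            + len(self.exogenous_covariances)
            + len(self.endogenous)
            + len(self.indicators)  # error variances
            + len(self.correlated_errors)
        )

    @property
    def df(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.n_free_parameters

    def to_yaml(self) -> str:
        import yaml

        blocks: dict[str, list[str]] = {l: [] for l in self.latents}
        for item, lat in self.indicators:
            blocks[lat].append(item)
        return yaml.safe_dump(
            {
                "latents": blocks,
                "paths": [f"{s} -> {t}" for s, t in self.structural_edges],
                "covariances": [f"{a} ~~ {b}" for a, b in self.exogenous_covariances],
                "correlated_errors": [f"{a} ~~ {b}" for a, b in self.correlated_errors],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SemModelSpec":
        import yaml

        d = yaml.safe_load(text)
        latents = tuple(d["latents"])
        indicators = tuple(
            (item, lat) for lat in latents for item in d["latents"][lat]
        )
        parse = lambda s, sep: tuple(x.strip() for x in s.split(sep))
        return cls(
            latents=latents,
            indicators=indicators,
            structural_edges=tuple(parse(e, "->") for e in d.get("paths", [])),
            exogenous_covariances=tuple(parse(e, "~~") for e in d.get("covariances", [])),
            correlated_errors=tuple(parse(e, "~~") for e in d.get("correlated_errors", [])),
        )


def build_default_spec(n_items: Mapping[str, int] | None = None) -> SemModelSpec:
    """The survey's model: 10/4/4/10 indicator blocks on the four latents,
    paths severity->php, preparedness->php, help->php, preparedness->help,
    and a free severity<->preparedness covariance (pure CFA if edges removed)."""
    n_items = dict(n_items or DEFAULT_N_ITEMS)
    names = item_names(n_items)
    indicators = []
    i = 0
    for lat in LATENTS:
        for _ in range(n_items[lat]):
            indicators.append((names[i], lat))
            i += 1
    return SemModelSpec(
        latents=LATENTS,
        indicators=tuple(indicators),
        structural_edges=(
            ("severity", "php"),
            ("preparedness", "php"),
            ("help", "php"),
            ("preparedness", "help"),
        ),
        exogenous_covariances=(("severity", "preparedness"),),
    )


@dataclass
class SemParams:
    """Full parameter matrices for a SemModelSpec (free and fixed entries)."""

    loadings: np.ndarray  # p x m
    beta: np.ndarray  # m x m, beta[target, source]
    psi: np.ndarray  # m x m latent (residual) covariance
    theta: np.ndarray  # p x p indicator error covariance


def _latent_index(spec: SemModelSpec) -> dict[str, int]:
    return {l: i for i, l in enumerate(spec.latents)}


def _item_index(spec: SemModelSpec) -> dict[str, int]:
    return {it: i for i, (it, _) in enumerate(spec.indicators)}


def _pack_template(spec: SemModelSpec):
    """Index arrays mapping the free-parameter vector onto the matrices."""
    li = _latent_index(spec)
    load_rows = np.arange(spec.n_observed)
    load_cols = np.array([li[lat] for _, lat in spec.indicators])
    b_idx = np.array(
        [(li[t], li[s]) for s, t in spec.structural_edges], dtype=int
    ).reshape(-1, 2)
    cov_idx = np.array(
        [(li[a], li[b]) for a, b in spec.exogenous_covariances], dtype=int
    ).reshape(-1, 2)
    resid_idx = np.array([li[l] for l in spec.endogenous], dtype=int)
    ii = _item_index(spec)
    cerr_idx = np.array(
        [(ii[a], ii[b]) for a, b in spec.correlated_errors], dtype=int
    ).reshape(-1, 2)
    return load_rows, load_cols, b_idx, cov_idx, resid_idx, cerr_idx


def _unpack(spec: SemModelSpec, theta_vec: np.ndarray) -> SemParams:
    p, m = spec.n_observed, len(spec.latents)
    load_rows, load_cols, b_idx, cov_idx, resid_idx, cerr_idx = _pack_template(spec)
    k = 0
    lam = np.zeros((p, m))
    lam[load_rows, load_cols] = theta_vec[k : k + p]
    k += p
    beta = np.zeros((m, m))
    for j, (t, s) in enumerate(b_idx):
        beta[t, s] = theta_vec[k + j]
    k += len(b_idx)
    psi = np.zeros((m, m))
    li = _latent_index(spec)
    for l in spec.exogenous:
        psi[li[l], li[l]] = 1.0
    for j, (a, b) in enumerate(cov_idx):
        psi[a, b] = psi[b, a] = theta_vec[k + j]
    k += len(cov_idx)
    for j, r in enumerate(resid_idx):
        psi[r, r] = theta_vec[k + j]
    k += len(resid_idx)
    theta_m = np.diag(theta_vec[k : k + p].copy())
    k += p
    for j, (a, b) in enumerate(cerr_idx):
        theta_m[a, b] = theta_m[b, a] = theta_vec[k + j]
    return SemParams(loadings=lam, beta=beta, psi=psi, theta=theta_m)


def implied_covariance(spec: SemModelSpec, params: SemParams) -> np.ndarray:
    """Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta."""
    m = len(spec.latents)
    imb = np.eye(m) - params.beta
    try:
        a = np.linalg.inv(imb)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "(I - B) is singular; the structural coefficients form a "
            f"non-invertible system: {params.beta}"
        ) from exc
    sig_l = a @ params.psi @ a.T
    sigma = params.loadings @ sig_l @ params.loadings.T + params.theta
    return (sigma + sigma.T) / 2.0


@dataclass
class SemFit:
    spec: SemModelSpec
    params: SemParams
    theta_vec: np.ndarray
    sample_cov: np.ndarray
    n: int
    fml: float
    chi_square: float
    df: int
    converged: bool
    n_iterations: int

    @property
    def implied(self) -> np.ndarray:
        return implied_covariance(self.spec, self.params)


def _fml_and_grad(
    theta_vec: np.ndarray,
    spec: SemModelSpec,
    s_mat: np.ndarray,
    logdet_s: float,
    template,
) -> tuple[float, np.ndarray]:
    p, m = spec.n_observed, len(spec.latents)
    load_rows, load_cols, b_idx, cov_idx, resid_idx, cerr_idx = template
    params = _unpack(spec, theta_vec)
    imb = np.eye(m) - params.beta
    a = np.linalg.inv(imb)
    sig_l = a @ params.psi @ a.T
    lam = params.loadings
    sigma = lam @ sig_l @ lam.T + params.theta
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e12, np.zeros_like(theta_vec)
    sig_inv = np.linalg.inv(sigma)
    fml = logdet + float(np.sum(sig_inv * s_mat)) - logdet_s - p
    # dF = tr(W dSigma), W = Sigma^-1 - Sigma^-1 S Sigma^-1
    w = sig_inv - sig_inv @ s_mat @ sig_inv
    grad = np.empty_like(theta_vec)
    k = 0
    wls = w @ lam @ sig_l  # p x m
    grad[k : k + p] = 2.0 * wls[load_rows, load_cols]
    k += p
    mmat = lam.T @ w @ lam  # m x m
    if len(b_idx):
        nmat = sig_l @ mmat @ a  # m x m; g for edge target t, source s = 2 N[s, t]
        for j, (t, s) in enumerate(b_idx):
            grad[k + j] = 2.0 * nmat[s, t]
    k += len(b_idx)
    amma = a.T @ mmat @ a
    for j, (ia, ib) in enumerate(cov_idx):
        grad[k + j] = 2.0 * amma[ia, ib]
    k += len(cov_idx)
    for j, r in enumerate(resid_idx):
        grad[k + j] = amma[r, r]
    k += len(resid_idx)
    grad[k : k + p] = np.diag(w)
    k += p
    for j, (ia, ib) in enumerate(cerr_idx):
        grad[k + j] = 2.0 * w[ia, ib]
    return fml, grad


def _start_values(spec: SemModelSpec, s_mat: np.ndarray) -> np.ndarray:
    p = spec.n_observed
    sd = np.sqrt(np.diag(s_mat))
    parts = [0.7 * sd]
    parts.append(np.zeros(len(spec.structural_edges)))
    parts.append(np.zeros(len(spec.exogenous_covariances)))
    parts.append(np.ones(len(spec.endogenous)))
    parts.append(0.5 * np.diag(s_mat))
    parts.append(np.zeros(len(spec.correlated_errors)))
    return np.concatenate(parts)


def _bounds(spec: SemModelSpec, s_mat: np.ndarray):
    p = spec.n_observed
    bounds: list[tuple] = [(None, None)] * p  # loadings
    bounds += [(None, None)] * len(spec.structural_edges)
    bounds += [(-0.999, 0.999)] * len(spec.exogenous_covariances)
    bounds += [(1e-6, None)] * len(spec.endogenous)
    floor = 1e-6 * float(np.median(np.diag(s_mat)))
    bounds += [(floor, None)] * p
    bounds += [(None, None)] * len(spec.correlated_errors)
    return bounds


def fit_ml(
    spec: SemModelSpec,
    sample_cov: np.ndarray | pd.DataFrame,
    n: int,
    *,
    max_restarts: int = 10,
    tol: float = 1e-10,
    seed: int = 0,
) -> SemFit:
    """Fit the model to a sample covariance matrix by maximum likelihood.

    Minimizes F_ML with L-BFGS-B using the analytic gradient; on
    non-convergence the start values are jittered and the fit restarted (up
    to ``max_restarts`` times).  The returned ``converged`` flag reports the
    optimizer's own status; a failed fit is returned flagged, never hidden.
    """
    if isinstance(sample_cov, pd.DataFrame):
        sample_cov = sample_cov.loc[list(spec.item_order), list(spec.item_order)].to_numpy()
    s_mat = np.asarray(sample_cov, dtype=float)
    p = spec.n_observed
    if s_mat.shape != (p, p):
        raise ValueError(f"sample covariance must be {p}x{p}")
    if not np.allclose(s_mat, s_mat.T, atol=1e-10):
        raise ValueError("sample covariance must be symmetric")
    sign, logdet_s = np.linalg.slogdet(s_mat)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")
    if n <= p:
        raise ValueError("sample size must exceed the number of observed variables")

    template = _pack_template(spec)
    x0 = _start_values(spec, s_mat)
    bounds = _bounds(spec, s_mat)
    rng = np.random.default_rng(seed)
    best = None
    n_iter_total = 0
    for attempt in range(max_restarts + 1):
        x_start = x0 if attempt == 0 else x0 * rng.uniform(0.7, 1.3, x0.size) + rng.normal(
            0, 0.05, x0.size
        )
        x_start = np.clip(
            x_start,
            [lo if lo is not None else -np.inf for lo, _ in bounds],
            [hi if hi is not None else np.inf for _, hi in bounds],
        )
        res = minimize(
            _fml_and_grad,
            x_start,
            args=(spec, s_mat, logdet_s, template),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-8},
        )
        n_iter_total += int(res.nit)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if res.success and res.fun < 1e10:
            best = res if res.fun <= best.fun else best
            break
    assert best is not None
    params = _unpack(spec, best.x)
    fml = float(best.fun)
    chi_sq = max((n - 1) * fml, 0.0)
    return SemFit(
        spec=spec,
        params=params,
        theta_vec=best.x.copy(),
        sample_cov=s_mat,
        n=int(n),
        fml=fml,
        chi_square=chi_sq,
        df=spec.df,
        converged=bool(best.success),
        n_iterations=n_iter_total,
    )


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitIndices:
    chi_square: float
    df: int
    chi_square_ratio: float
    rmsea: float
    cfi: Optional[float]
    baseline_chi_square: Optional[float] = None
    baseline_df: Optional[int] = None


def fit_indices_from_stats(
    chi_square: float,
    df: int,
    n: int,
    baseline_chi_square: float | None = None,
    baseline_df: int | None = None,
) -> FitIndices:
    """Closed-form fit indices from the chi-square statistic.

    ratio = chi^2/df; RMSEA = sqrt(max(chi^2 - df, 0) / (df (n-1)));
    CFI = 1 - max(chi^2_M - df_M, 0) / max(chi^2_B - df_B, chi^2_M - df_M, 0)
    (CFI is None when no baseline is supplied).  chi^2 <= df gives RMSEA 0
    and CFI 1.
    """
    if df <= 0:
        raise ValueError("fit indices are undefined for df <= 0")
    ratio = chi_square / df
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    cfi = None
    if baseline_chi_square is not None and baseline_df is not None:
        num = max(chi_square - df, 0.0)
        den = max(baseline_chi_square - baseline_df, chi_square - df, 0.0)
        cfi = 1.0 if den == 0.0 else 1.0 - num / den
    return FitIndices(
        chi_square=chi_square,
        df=df,
        chi_square_ratio=ratio,
        rmsea=rmsea,
        cfi=cfi,
        baseline_chi_square=baseline_chi_square,
        baseline_df=baseline_df,
    )


def fit_indices(fit: SemFit) -> FitIndices:
    """Fit indices of a fitted model, CFI against the independence baseline
    (diagonal Sigma with free variances, whose ML solution is diag(S))."""
    if not fit.converged:
        warnings.warn("fit did not converge; indices may be meaningless")
    s_mat = fit.sample_cov
    p = s_mat.shape[0]
    _, logdet_s = np.linalg.slogdet(s_mat)
    f_base = float(np.sum(np.log(np.diag(s_mat))) - logdet_s)
    chi_base = max((fit.n - 1) * f_base, 0.0)
    df_base = p * (p - 1) // 2
    return fit_indices_from_stats(fit.chi_square, fit.df, fit.n, chi_base, df_base)


# ---------------------------------------------------------------------------
# Standardized solution, effects, R^2
# ---------------------------------------------------------------------------


@dataclass
class StandardizedSolution:
    loadings: pd.Series  # item -> standardized loading
    paths: dict[tuple[str, str], float]  # (source, target) -> coefficient
    exo_correlations: dict[tuple[str, str], float]
    residual_variances: dict[str, float]  # endogenous latent -> standardized
    beta_std: np.ndarray  # m x m, [target, source]


def standardized_solution(fit: SemFit) -> StandardizedSolution:
    """Rescale every latent and observed variable to unit variance.

    Standardized coefficients are invariant to rescaling any indicator by a
    positive constant, which is why the published report could print them
    without the raw metric.
    """
    spec = fit.spec
    li = _latent_index(spec)
    m = len(spec.latents)
    imb = np.eye(m) - fit.params.beta
    a = np.linalg.inv(imb)
    sig_l = a @ fit.params.psi @ a.T
    d_l = np.sqrt(np.diag(sig_l))
    sigma = fit.implied
    d_obs = np.sqrt(np.diag(sigma))
    if np.any(d_l <= 0) or np.any(d_obs <= 0):
        raise ValueError("zero estimated variance; standardization undefined")
    lam_std = fit.params.loadings * (d_l[None, :] / d_obs[:, None])
    load = pd.Series(
        {it: lam_std[i, li[lat]] for i, (it, lat) in enumerate(spec.indicators)}
    )
    beta_std = fit.params.beta * (d_l[None, :] / d_l[:, None])
    paths = {
        (s, t): float(beta_std[li[t], li[s]]) for s, t in spec.structural_edges
    }
    exo_corr = {
        (a_, b_): float(fit.params.psi[li[a_], li[b_]] / (d_l[li[a_]] * d_l[li[b_]]))
        for a_, b_ in spec.exogenous_covariances
    }
    resid = {
        l: float(fit.params.psi[li[l], li[l]] / sig_l[li[l], li[l]])
        for l in spec.endogenous
    }
    return StandardizedSolution(
        loadings=load,
        paths=paths,
        exo_correlations=exo_corr,
        residual_variances=resid,
        beta_std=beta_std,
    )


@dataclass
class EffectTable:
    """Direct / indirect / total standardized effects between latents.

    IE sums coefficient products over every directed path of length >= 2;
    TE = DE + IE holds exactly by construction.
    """

    latents: tuple[str, ...]
    direct: dict[tuple[str, str], float]
    indirect: dict[tuple[str, str], float]

    def total(self, source: str, target: str) -> float:
        key = (source, target)
        return self.direct.get(key, 0.0) + self.indirect.get(key, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        keys = sorted(set(self.direct) | set(self.indirect))
        for s, t in keys:
            de = self.direct.get((s, t), 0.0)
            ie = self.indirect.get((s, t), 0.0)
            rows.append({"source": s, "target": t, "DE": de, "IE": ie, "TE": de + ie})
        return pd.DataFrame(rows)


def effects_from_paths(
    paths: Mapping[tuple[str, str], float], latents: Sequence[str] = LATENTS
) -> EffectTable:
    """Effect decomposition from standardized path coefficients alone."""
    li = {l: i for i, l in enumerate(latents)}
    m = len(latents)
    b = np.zeros((m, m))
    for (s, t), v in paths.items():
        b[li[t], li[s]] = v
    total = np.linalg.inv(np.eye(m) - b) - np.eye(m)
    indirect = total - b
    direct = {(s, t): float(v) for (s, t), v in paths.items()}
    ind = {}
    for s in latents:
        for t in latents:
            v = indirect[li[t], li[s]]
            if abs(v) > 0.0:
                ind[(s, t)] = float(v)
    return EffectTable(latents=tuple(latents), direct=direct, indirect=ind)


def effect_decomposition(fit: SemFit) -> EffectTable:
    std = standardized_solution(fit)
    return effects_from_paths(std.paths, fit.spec.latents)


def squared_multiple_correlations(fit: SemFit) -> dict[str, float]:
    """R^2 = 1 - standardized residual variance, per endogenous latent."""
    std = standardized_solution(fit)
    return {l: 1.0 - v for l, v in std.residual_variances.items()}


# ---------------------------------------------------------------------------
# Cross-module bridge
# ---------------------------------------------------------------------------


def params_from_generator_config(config: GeneratorConfig, spec: SemModelSpec) -> SemParams:
    """Exact SemParams of the generating model of ``synthetic_data`` (the
    population values on the pre-discretization scale), for use as a
    zero-discrepancy oracle."""
    from .synthetic_data import _structural_matrices

    li = _latent_index(spec)
    p = spec.n_observed
    lam = np.zeros((p, len(spec.latents)))
    for i, (_, lat) in enumerate(spec.indicators):
        lam[i, li[lat]] = config.measurement_loading
    b_gen, psi_gen = _structural_matrices(config)
    theta = np.eye(p) * (1.0 - config.measurement_loading**2)
    return SemParams(loadings=lam, beta=b_gen, psi=psi_gen, theta=theta)


def fit_summary_text(fit: SemFit) -> str:
    """Plain-text fit report mirroring the published effect-table layout."""
    std = standardized_solution(fit)
    eff = effect_decomposition(fit)
    idx = fit_indices(fit)
    smc = squared_multiple_correlations(fit)
    lines = ["Effects between independent and dependent variables", ""]
    lines.append(f"{'source':>14} {'target':>14} {'TE':>8} {'IE':>8} {'DE':>8}")
    for _, row in eff.to_dataframe().iterrows():
        lines.append(
            f"{row['source']:>14} {row['target']:>14} "
            f"{row['TE']:8.3f} {row['IE']:8.3f} {row['DE']:8.3f}"
        )
    lines += [
        "",
        f"chi-square = {fit.chi_square:.3f}, df = {fit.df}, "
        f"chi-square/df = {idx.chi_square_ratio:.3f}",
        f"CFI = {idx.cfi:.3f}, RMSEA = {idx.rmsea:.3f}"
        if idx.cfi is not None
        else f"RMSEA = {idx.rmsea:.3f}",
        "",
        "Squared multiple correlations: "
        + ", ".join(f"{l} = {100 * v:.1f}%" for l, v in smc.items()),
        f"converged = {fit.converged} ({fit.n_iterations} iterations)",
    ]
    return "\n".join(lines)
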