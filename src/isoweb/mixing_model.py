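"""Bayesian two-tracer diet mixing model.

The model estimates the proportional contribution p of each food source to a
consumer population's tissue signature. For consumer j and tracer k the
observed value is

    x_jk ~ Normal(mu_jk, s_jk)
    mu_jk   = sum_i p_ji (mu_S,ik + mu_TDF,k)
    s_jk^2  = xi_k * sum_i p_ji^2 (sigma_S,ik^2 + sigma_TDF,k^2)

with a global diet p ~ Dirichlet(alpha) and, optionally, per-consumer diets
p_j obtained by perturbing the isometric log-ratio (ILR) transform of p with
Normal(0, sigma_re) deviations (a consumer random effect), and a
multiplicative error scale xi_k per tracer inflating the propagated
source+TDF variance. Priors: xi_k ~ Uniform(0, 20), sigma_re ~ Half-Normal(1)
— wide, weakly informative defaults.

Posterior sampling uses blocked adaptive random-walk Metropolis on
unconstrained coordinates (ILR of p, the per-consumer ILR deviations, log xi,
log sigma_re). Proposal scales adapt by Robbins–Monro toward acceptance rates
in the 0.23–0.44 range during burn-in and are frozen afterwards. Convergence
is checked with split-chain Gelman–Rubin R-hat (< 1.1) and the Geweke
early/late-window z-score; model comparison uses PSIS-LOO or WAIC on the
deviance scale with Akaike-type pseudo-weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert

from .data_io import IsotopeMeasurement, SourceSummary
from .errors import (
    ComparisonError,
    InsufficientDataError,
    SamplerError,
    ValidationError,
)
from .priors import DirichletPrior
from .tdf import TDFSpec

TRACERS = ("d13C", "d15N")

_VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# isometric log-ratio transform (orthonormal Helmert basis)

from functools import lru_cache


@lru_cache(maxsize=None)
def _basis(n: int) -> np.ndarray:
    return helmert(n)  # (n-1, n), rows orthonormal, orthogonal to ones


def ilr(p: np.ndarray) -> np.ndarray:
    """ILR transform of composition(s) ``p`` (last axis on the simplex)."""
    p = np.asarray(p, dtype=float)
    logp = np.log(np.clip(p, 1e-300, None))
    return logp @ _basis(p.shape[-1]).T


def ilr_inv(z: np.ndarray, n: Optional[int] = None) -> np.ndarray:
    """Inverse ILR: map real coordinates back to the simplex (softmax)."""
    z = np.asarray(z, dtype=float)
    n = z.shape[-1] + 1 if n is None else n
    x = z @ _basis(n)
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# model specification and posterior container

@dataclass
class MixingModelSpec:
    """Everything that defines one mixing model (data-independent)."""

    sources: list[SourceSummary]
    tdf: TDFSpec
    prior: DirichletPrior
    error_model: str = "multiplicative"  # | "process_only"
    random_effect: str = "consumer"  # | "none"
    tracers: tuple[str, ...] = TRACERS
    name: str = "model"

    def __post_init__(self) -> None:
        if self.error_model not in ("multiplicative", "process_only"):
            raise ValidationError(f"unknown error_model {self.error_model!r}")
        if self.random_effect not in ("consumer", "none"):
            raise ValidationError(f"unknown random_effect {self.random_effect!r}")
        if not self.tracers:
            raise ValidationError("at least one tracer required")
        names = [s.name for s in self.sources]
        if list(self.prior.source_names) != names:
            raise ValidationError(
                "prior source names must match the source list order"
            )

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


@dataclass
class DietPosterior:
    """MCMC draws, summaries and diagnostics of one fitted mixing model."""

    spec: MixingModelSpec
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    log_likelihood: Optional[np.ndarray] = None  # (chains, draws, consumers)
    summary: Optional[pd.DataFrame] = None
    diagnostics: Optional[pd.DataFrame] = None
    converged: bool = True
    consumer_ids: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def p_mean(self) -> np.ndarray:
        """Posterior mean of the global diet proportions."""
        p = self.draws["p"]
        return p.reshape(-1, p.shape[-1]).mean(axis=0)

    def p_interval(self, level: float = 0.95) -> np.ndarray:
        """Central credible interval of each global proportion, (n_src, 2)."""
        p = self.draws["p"].reshape(-1, self.draws["p"].shape[-1])
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return np.quantile(p, [lo, hi], axis=0).T

    def save_draws(self, path) -> None:
        """Long-format draws file: chain,iteration,parameter,value."""
        rows = []
        for pname, values in self._scalar_views().items():
            c, d = values.shape
            for ci in range(c):
                rows.append(pd.DataFrame({
                    "chain": ci, "iteration": np.arange(d),
                    "parameter": pname, "value": values[ci],
                }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)

    def _scalar_views(self) -> dict[str, np.ndarray]:
        """Named scalar traces, each (chains, draws)."""
        out = {}
        p = self.draws.get("p")
        if p is not None:
            for i, s in enumerate(self.spec.source_names):
                out[f"p[{s}]"] = p[..., i]
        xi = self.draws.get("xi")
        if xi is not None:
            for k, tr in enumerate(self.spec.tracers):
                out[f"xi[{tr}]"] = xi[..., k]
        if "sigma_re" in self.draws:
            out["sigma_re"] = self.draws["sigma_re"]
        return out


# ---------------------------------------------------------------------------
# log-density pieces

class _Model:
    """Precomputed arrays and log-density evaluations for one dataset."""

    def __init__(self, spec: MixingModelSpec, consumers: Sequence[IsotopeMeasurement]):
        self.spec = spec
        K = len(spec.tracers)
        n = len(spec.sources)
        self.x = np.empty((len(consumers), K))
        for j, c in enumerate(consumers):
            for k, tr in enumerate(spec.tracers):
                v = getattr(c, tr, None)
                if v is None or not np.isfinite(v):
                    raise ValidationError(
                        f"consumer {c.sample_id}: tracer {tr} missing or non-finite"
                    )
                self.x[j, k] = v
        self.M = np.array(
            [[s.mean(tr) + spec.tdf.mean(tr) for tr in spec.tracers] for s in spec.sources]
        )  # (n, K)
        self.V = np.array(
            [[s.sd(tr) ** 2 + spec.tdf.sd(tr) ** 2 for tr in spec.tracers] for s in spec.sources]
        )  # (n, K)
        self.alpha = np.asarray(spec.prior.alpha, dtype=float)
        self.J, self.K, self.n = len(consumers), K, n
        self.d = n - 1

    def loglik_rows(self, p_all: np.ndarray, xi: np.ndarray) -> np.ndarray:
        """Per-consumer per-tracer Gaussian log-likelihood, (J, K)."""
        mu = p_all @ self.M
        var = xi[None, :] * (p_all**2 @ self.V)
        var = np.maximum(var, _VAR_FLOOR)
        return -0.5 * (np.log(2 * np.pi * var) + (self.x - mu) ** 2 / var)

    def log_dirichlet_ilr(self, z: np.ndarray) -> float:
        """Dirichlet(alpha) prior density on ILR coordinates (incl. Jacobian)."""
        g = ilr_inv(z, self.n)
        return float(self.alpha @ np.log(np.clip(g, 1e-300, None)))


def _halfnormal_logpdf_logscale(lsig: float) -> float:
    # log p(log sigma) for sigma ~ HalfNormal(1), including the Jacobian
    sig = np.exp(lsig)
    return -0.5 * sig**2 + lsig


def _xi_logprior_logscale(lxi: float, upper: float = 20.0) -> float:
    # xi ~ Uniform(0, upper) sampled on the log scale
    xi = np.exp(lxi)
    return lxi if xi < upper else -np.inf


# ---------------------------------------------------------------------------
# sampler

def fit(
    spec: MixingModelSpec,
    consumers: Sequence[IsotopeMeasurement],
    chains: int = 3,
    iterations: int = 30_000,
    burn: int = 15_000,
    thin: int = 10,
    seed: Optional[int] = None,
) -> DietPosterior:
    """Sample the diet posterior by blocked adaptive random-walk Metropolis.

    ``seed`` is required; each chain gets an independent child seed. Returns
    retained (post-burn, thinned) draws plus summaries, split-R-hat and
    Geweke diagnostics, and pointwise log-likelihoods for LOO/WAIC.
    """
    if seed is None:
        raise ValueError("fit: a seed is required (no silent default)")
    if iterations <= burn:
        raise ValidationError("iterations must exceed burn")
    if not consumers:
        raise ValidationError("fit: no consumers supplied")

    n = len(spec.sources)
    if n == 1:
        return _degenerate_single_source(spec, consumers, chains, iterations, burn, thin, seed)

    model = _Model(spec, consumers)
    use_re = spec.random_effect == "consumer"
    use_xi = spec.error_model == "multiplicative"

    n_keep = (iterations - burn) // thin
    if n_keep < 1:
        raise ValidationError("no draws retained; reduce thin or raise iterations")

    child_seeds = np.random.SeedSequence(seed).spawn(chains)
    p_draws = np.empty((chains, n_keep, n))
    pc_draws = np.empty((chains, n_keep, model.J, n))
    xi_draws = np.empty((chains, n_keep, model.K))
    sig_draws = np.empty((chains, n_keep))
    ll_draws = np.empty((chains, n_keep, model.J))

    for ci in range(chains):
        rng = np.random.default_rng(child_seeds[ci])
        _run_chain(
            model, rng, iterations, burn, thin, use_re, use_xi,
            p_draws[ci], pc_draws[ci], xi_draws[ci], sig_draws[ci], ll_draws[ci],
        )

    draws = {"p": p_draws, "p_consumer": pc_draws, "xi": xi_draws}
    if use_re:
        draws["sigma_re"] = sig_draws
    post = DietPosterior(
        spec=spec, draws=draws, log_likelihood=ll_draws,
        consumer_ids=[c.sample_id for c in consumers],
        settings={"chains": chains, "iterations": iterations, "burn": burn,
                  "thin": thin, "seed": seed},
    )
    _summarize(post)
    return post


def _run_chain(model, rng, iterations, burn, thin, use_re, use_xi,
               p_out, pc_out, xi_out, sig_out, ll_out):
    J, K, d, n = model.J, model.K, model.d, model.n

    z = ilr(model.alpha / model.alpha.sum()) + 0.2 * rng.standard_normal(d)
    eta = np.zeros((J, d))
    lxi = np.zeros(K)
    lsig = np.log(0.3)

    # adaptive log proposal scales
    ls_z, ls_e = np.log(0.2), np.log(0.2)
    ls_x = np.full(K, np.log(0.5))
    ls_s = np.log(0.5)

    def state_eval(z, eta, lxi, lsig):
        p_all = ilr_inv(z[None, :] + eta, n)
        xi = np.exp(lxi) if use_xi else np.ones(K)
        ll = model.loglik_rows(p_all, xi)
        return p_all, ll

    p_all, ll = state_eval(z, eta, lxi, lsig)
    lp_z = model.log_dirichlet_ilr(z)
    kept = 0
    for t in range(1, iterations + 1):
        gam = min(0.25, t ** -0.6)
        adapting = t <= burn
        sig2 = np.exp(2 * lsig)

        # --- global composition block
        z_prop = z + np.exp(ls_z) * rng.standard_normal(d)
        p_prop = ilr_inv(z_prop[None, :] + eta, n)
        xi_now = np.exp(lxi) if use_xi else np.ones(K)
        ll_prop = model.loglik_rows(p_prop, xi_now)
        lp_prop = model.log_dirichlet_ilr(z_prop)
        delta = ll_prop.sum() - ll.sum() + lp_prop - lp_z
        if np.log(rng.random()) < delta:
            z, p_all, ll, lp_z = z_prop, p_prop, ll_prop, lp_prop
            acc = 1.0
        else:
            acc = float(np.exp(min(0.0, delta)))
        if adapting:
            ls_z += gam * (acc - 0.28)

        # --- per-consumer deviations (vectorized, independent accept/reject)
        if use_re:
            eta_prop = eta + np.exp(ls_e) * rng.standard_normal((J, d))
            p_prop = ilr_inv(z[None, :] + eta_prop, n)
            ll_prop = model.loglik_rows(p_prop, xi_now)
            dprior = ((eta**2).sum(axis=1) - (eta_prop**2).sum(axis=1)) / (2 * sig2)
            delta_j = ll_prop.sum(axis=1) - ll.sum(axis=1) + dprior
            accept = np.log(rng.random(J)) < delta_j
            eta[accept] = eta_prop[accept]
            p_all[accept] = p_prop[accept]
            ll[accept] = ll_prop[accept]
            if adapting:
                rate = float(np.exp(np.minimum(0.0, delta_j)).mean())
                ls_e += gam * (rate - 0.28)

        # --- error scales (one scalar update per tracer)
        if use_xi:
            for k in range(K):
                lxi_prop = lxi.copy()
                lxi_prop[k] = lxi[k] + np.exp(ls_x[k]) * rng.standard_normal()
                pr_prop = _xi_logprior_logscale(lxi_prop[k])
                if np.isfinite(pr_prop):
                    xi_prop = np.exp(lxi_prop)
                    ll_prop = model.loglik_rows(p_all, xi_prop)
                    delta = (ll_prop[:, k].sum() - ll[:, k].sum()
                             + pr_prop - _xi_logprior_logscale(lxi[k]))
                else:
                    delta = -np.inf
                if np.log(rng.random()) < delta:
                    lxi = lxi_prop
                    ll = ll_prop
                    acc = 1.0
                else:
                    acc = float(np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
                if adapting:
                    ls_x[k] += gam * (acc - 0.44)

        # --- random-effect scale (conjugate-free scalar update)
        if use_re:
            lsig_prop = lsig + np.exp(ls_s) * rng.standard_normal()
            ssq = float((eta**2).sum())
            def _lp_sig(ls):
                s2 = np.exp(2 * ls)
                return -0.5 * J * d * np.log(s2) - ssq / (2 * s2) + _halfnormal_logpdf_logscale(ls)
            delta = _lp_sig(lsig_prop) - _lp_sig(lsig)
            if np.log(rng.random()) < delta:
                lsig = lsig_prop
                acc = 1.0
            else:
                acc = float(np.exp(min(0.0, delta)))
            if adapting:
                ls_s += gam * (acc - 0.44)

        if t > burn and (t - burn) % thin == 0:
            if kept < p_out.shape[0]:
                p_out[kept] = ilr_inv(z, n)
                pc_out[kept] = p_all
                xi_out[kept] = np.exp(lxi) if use_xi else 1.0
                sig_out[kept] = np.exp(lsig)
                ll_out[kept] = ll.sum(axis=1)
                kept += 1
    if not np.all(np.isfinite(p_out)):
        raise SamplerError("non-finite draws produced; check inputs")


def _degenerate_single_source(spec, consumers, chains, iterations, burn, thin, seed):
    """With one source the simplex forces p = 1; no sampling is needed."""
    model = _Model(spec, consumers)
    n_keep = max(1, (iterations - burn) // thin)
    p = np.ones((chains, n_keep, 1))
    ll_row = model.loglik_rows(np.ones((model.J, 1)), np.ones(model.K)).sum(axis=1)
    post = DietPosterior(
        spec=spec,
        draws={"p": p, "p_consumer": np.ones((chains, n_keep, model.J, 1)),
               "xi": np.ones((chains, n_keep, model.K))},
        log_likelihood=np.broadcast_to(ll_row, (chains, n_keep, model.J)).copy(),
        consumer_ids=[c.sample_id for c in consumers],
        settings={"chains": chains, "iterations": iterations, "burn": burn,
                  "thin": thin, "seed": seed, "degenerate": True},
    )
    post.summary = pd.DataFrame(
        [{"parameter": f"p[{spec.source_names[0]}]", "mean": 1.0, "sd": 0.0,
          "q2.5": 1.0, "median": 1.0, "q97.5": 1.0}]
    )
    post.diagnostics = pd.DataFrame(
        [{"parameter": f"p[{spec.source_names[0]}]", "rhat": 1.0, "geweke_z": 0.0}]
    )
    return post


def _summarize(post: DietPosterior) -> None:
    rows, diag_rows = [], []
    all_ok = True
    for pname, tr in post._scalar_views().items():
        flat = tr.reshape(-1)
        q = np.quantile(flat, [0.025, 0.5, 0.975])
        rows.append({"parameter": pname, "mean": flat.mean(), "sd": flat.std(ddof=1),
                     "q2.5": q[0], "median": q[1], "q97.5": q[2]})
        rhat = float(gelman_rubin(tr)) if tr.shape[0] >= 2 else np.nan
        try:
            gz = float(max(abs(geweke(tr[c])) for c in range(tr.shape[0])))
        except InsufficientDataError:
            gz = np.nan
        diag_rows.append({"parameter": pname, "rhat": rhat, "geweke_z": gz})
        if np.isfinite(rhat) and rhat >= 1.1:
            all_ok = False
    post.summary = pd.DataFrame(rows)
    post.diagnostics = pd.DataFrame(diag_rows)
    post.converged = all_ok


# ---------------------------------------------------------------------------
# convergence diagnostics

def gelman_rubin(draws: np.ndarray) -> np.ndarray | float:
    """Split-chain Gelman–Rubin R-hat.

    ``draws`` has shape (chains, iterations) or (chains, iterations, params);
    each chain is split in half before the between/within variance ratio is
    formed. Returns a scalar or a per-parameter vector.
    """
    a = np.asarray(draws, dtype=float)
    if a.ndim == 2:
        return float(_rhat_single(a))
    if a.ndim == 3:
        return np.array([_rhat_single(a[:, :, i]) for i in range(a.shape[2])])
    raise ValidationError("draws must be (chains, iters) or (chains, iters, params)")


def _rhat_single(a: np.ndarray) -> float:
    m, n = a.shape
    if m < 2:
        raise InsufficientDataError("gelman_rubin needs >= 2 chains")
    if n < 10:
        raise InsufficientDataError("gelman_rubin needs >= 10 draws per chain")
    half = n // 2
    split = np.concatenate([a[:, :half], a[:, half: 2 * half]], axis=0)
    m2, n2 = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_hat / W))


def geweke(chain: np.ndarray, first_frac: float = 0.10, last_frac: float = 0.50) -> float:
    """Geweke convergence z-score for one chain.

    Compares the mean of the first ``first_frac`` of the chain against the
    mean of the last ``last_frac``, with window variances estimated from the
    spectral density at frequency zero (AR model selected by AIC, as in the
    classical implementation). |z| < 1.96 is consistent with stationarity.
    """
    if first_frac <= 0 or last_frac <= 0 or first_frac + last_frac > 1:
        raise ValidationError("need first_frac, last_frac > 0 and their sum <= 1")
    x = np.asarray(chain, dtype=float)
    n = x.size
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("geweke windows too small")
    a, b = x[:n1], x[n - n2:]
    s1, s2 = _spectrum0(a), _spectrum0(b)
    denom = s1 / n1 + s2 / n2
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero via an AIC-selected AR fit."""
    if np.ptp(x) == 0:
        return 0.0
    from statsmodels.tsa.ar_model import ar_select_order

    maxlag = int(min(10 * np.log10(x.size), x.size / 2 - 2))
    if maxlag < 1:
        return float(np.var(x, ddof=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = ar_select_order(x, maxlag=maxlag, ic="aic", trend="c")
        res = sel.model.fit()
    phi = np.asarray(res.params)[1:]  # trend 'c' puts the constant first
    denom = (1.0 - phi.sum()) ** 2
    if denom <= 0:
        return float(np.var(x, ddof=1))
    return float(res.sigma2 / denom)


# ---------------------------------------------------------------------------
# model comparison

def compare(models: Sequence[DietPosterior], method: str = "loo") -> pd.DataFrame:
    """Rank fitted models by PSIS-LOO or WAIC (deviance scale).

    All models must have been fitted to the identical consumer set. Returns a
    table sorted ascending by the criterion with columns named after the
    conventional LOO comparison layout: LOOic, se_LOOic, dLOOic, se_dLOOic
    and an Akaike-type pseudo-weight proportional to exp(-dLOOic/2)
    (WAIC/se_WAIC/... when ``method='waic'``).
    """
    import arviz as az

    if method not in ("loo", "waic"):
        raise ValidationError(f"unknown comparison method {method!r}")
    if not models:
        raise ComparisonError("no models to compare")
    ids0 = models[0].consumer_ids
    for m in models[1:]:
        if m.consumer_ids != ids0:
            raise ComparisonError("models were fitted to different consumer sets")

    ics, ses, pointwise = [], [], []
    for m in models:
        if m.log_likelihood is None:
            raise ComparisonError(f"model {m.spec.name}: no pointwise log-likelihood stored")
        idata = az.from_dict(
            posterior={"p": m.draws["p"]},
            log_likelihood={"y": m.log_likelihood},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "loo":
                res = az.loo(idata, pointwise=True, scale="deviance")
                ic, se, pw = res.elpd_loo, res.se, np.asarray(res.loo_i)
            else:
                res = az.waic(idata, pointwise=True, scale="deviance")
                ic, se, pw = res.elpd_waic, res.se, np.asarray(res.waic_i)
        ics.append(float(ic))
        ses.append(float(se))
        pointwise.append(pw)

    ics = np.array(ics)
    best = int(np.argmin(ics))
    nobs = len(ids0)
    d = ics - ics[best]
    se_d = np.empty(len(models))
    for i, pw in enumerate(pointwise):
        if i == best:
            se_d[i] = np.nan
        else:
            diff = pw - pointwise[best]
            se_d[i] = float(np.sqrt(nobs * np.var(diff, ddof=1))) if nobs > 1 else np.nan
    w = np.exp(-0.5 * d)
    w = w / w.sum()

    prefix = "LOOic" if method == "loo" else "WAIC"
    table = pd.DataFrame({
        "model": [m.spec.name for m in models],
        prefix: ics,
        f"se_{prefix}": ses,
        f"d{prefix}": d,
        f"se_d{prefix}": se_d,
        "weight": w,
    })
    return table.sort_values(prefix, kind="stable").reset_index(drop=True)
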