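"""Posterior inference: NUTS over the joint model, diagnostics, summaries.

All continuous parameters (regression coefficients, mixture weights,
CAR parameters and the shared field) are sampled jointly by NUTS on an
unconstrained scale: logits for the mixture weights alpha_i and the
spatial dependence lambda_G, log for the precision tau.  Missing
Bernoulli responses are marginalized analytically — a missing cell's
observation factor integrates to one — which is exactly equivalent to
sampling the missing outcomes as discrete parameters; their posterior
presence probabilities are reconstructed afterwards from the latent
Q_i / S draws (:func:`impute_missing`).

The fused log-density/gradient below is algebraically identical to
:func:`pojsdm.model.joint_log_posterior` plus the change-of-variable
Jacobians, which the tests verify against finite differences and the
reference implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az
from scipy.special import expit, betaln, gammaln

from .lattice import MISSING
from .model import ModelData, ModelParams, Priors, CarStructure
from .sampler import nuts

__all__ = ["FitConfig", "PosteriorSample", "fit", "rhat", "ess",
           "summarize", "impute_missing"]

_CLIP = 1e-12


@dataclass
class FitConfig:
    """Sampler configuration.

    Defaults mirror the reference analysis protocol (4 chains of
    35 000 iterations, burn-in 17 500, thinning 35); test suites use
    much shorter chains via the same fields.  ``iterations`` counts all
    iterations per chain including burn-in.
    """

    chains: int = 4
    iterations: int = 35_000
    burn_in: int = 17_500
    thinning: int = 35
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self):
        if not (0 < self.burn_in < self.iterations):
            raise ValueError("need 0 < burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) \
            // self.thinning

    @classmethod
    def from_json(cls, path_or_str) -> "FitConfig":
        import json

        try:
            obj = json.loads(path_or_str)
        except (ValueError, TypeError):
            with open(path_or_str) as fh:
                obj = json.load(fh)
        return cls(**obj)


class _Posterior:
    """Packed unconstrained posterior with analytic gradients."""

    def __init__(self, data: ModelData, priors: Priors,
                 alpha_fixed=None):
        data.validate()
        self.data = data
        self.priors = priors
        self.car = CarStructure(data.adjacency)
        n, nc = data.n_taxa, data.n_cells
        self.n_taxa, self.n_cells = n, nc
        self.pe, self.ps = data.p_eco, data.p_samp

        self.obs_y = data.y != MISSING                      # (n, nc)
        self.yf = np.where(self.obs_y, data.y, 0).astype(float)
        self.obs_c = (data.y_c != MISSING).astype(float)    # (nc,)
        self.ycf = np.where(data.y_c != MISSING, data.y_c, 0).astype(float)

        if alpha_fixed is None:
            alpha_fixed = np.full(n, np.nan)
        self.alpha_fixed = np.asarray(alpha_fixed, dtype=float)
        if self.alpha_fixed.shape != (n,):
            raise ValueError("alpha_fixed must have one entry per taxon "
                             "(NaN = sampled)")
        self.free_alpha = np.isnan(self.alpha_fixed)

        # theta layout: beta_p | beta_s | a(free) | l | t | G
        self.n_bp = n * self.pe
        self.n_free_a = int(self.free_alpha.sum())
        self.i_bs = self.n_bp
        self.i_a = self.i_bs + self.ps
        self.i_l = self.i_a + self.n_free_a
        self.i_t = self.i_l + 1
        self.i_g = self.i_t + 1
        self.dim = self.i_g + nc

        self.W = self.car.W
        self.deg = self.car.degrees

    # -- packing -------------------------------------------------------
    def unpack(self, theta: np.ndarray) -> ModelParams:
        alpha = self.alpha_fixed.copy()
        alpha[self.free_alpha] = expit(theta[self.i_a:self.i_l])
        return ModelParams(
            beta_p=theta[: self.n_bp].reshape(self.n_taxa, self.pe),
            beta_s=theta[self.i_bs:self.i_a],
            alpha=alpha,
            lambda_g=float(expit(theta[self.i_l])),
            tau=float(np.exp(theta[self.i_t])),
            g=theta[self.i_g:],
        )

    def initial(self, rng) -> np.ndarray:
        theta = np.zeros(self.dim)
        theta[: self.i_g] = rng.normal(scale=0.3, size=self.i_g)
        theta[self.i_g:] = rng.normal(scale=0.1, size=self.n_cells)
        return theta

    # -- density + gradient -------------------------------------------
    def logp_grad(self, theta: np.ndarray):
        d = self.data
        pr = self.priors
        n, nc = self.n_taxa, self.n_cells
        B = theta[: self.n_bp].reshape(n, self.pe)
        bs = theta[self.i_bs:self.i_a]
        a_free = theta[self.i_a:self.i_l]
        l = theta[self.i_l]
        t = theta[self.i_t]
        G = theta[self.i_g:]

        alpha = self.alpha_fixed.copy()
        alpha[self.free_alpha] = expit(a_free)
        lam = float(expit(l))
        lam = min(max(lam, 1e-12), 1.0 - 1e-9)
        with np.errstate(over="ignore"):
            tau = float(np.exp(t))
        if tau <= 0.0 or not np.isfinite(tau):
            # exp under/overflow on a wild trajectory: reject the point
            return -np.inf, np.zeros(self.dim)

        grad = np.zeros(self.dim)
        gG = np.zeros(nc)
        logp = 0.0

        # sampling-effort process
        eta_s = d.design_samp @ bs + G
        S = expit(eta_s)
        # complementary likelihood, logit-stable form
        logp += float(np.sum(self.obs_c * (self.ycf * eta_s
                                           - np.logaddexp(0.0, eta_s))))
        g_eta_s = self.obs_c * (self.ycf - S)
        mix_acc = np.zeros(nc)  # sum_i m_i r_i (1 - alpha_i)
        g_alpha = np.zeros(n)

        for i in range(n):
            De = d.design_eco_for(i)
            eta = De @ B[i] + G
            P = expit(eta)
            Q = alpha[i] * P + (1.0 - alpha[i]) * S
            Qc = np.clip(Q, _CLIP, 1.0 - _CLIP)
            m = self.obs_y[i]
            y = self.yf[i]
            logp += float(np.sum(np.where(
                m, y * np.log(Qc) + (1.0 - y) * np.log1p(-Qc), 0.0)))
            r = np.where(m, (y - Qc) / (Qc * (1.0 - Qc)), 0.0)
            g_eta_p = r * (alpha[i] * P * (1.0 - P))
            grad[i * self.pe:(i + 1) * self.pe] = De.T @ g_eta_p
            gG += g_eta_p
            g_alpha[i] = float(np.sum(r * (P - S)))
            mix_acc += r * (1.0 - alpha[i])

        g_eta_s = g_eta_s + mix_acc * S * (1.0 - S)
        grad[self.i_bs:self.i_a] = d.design_samp.T @ g_eta_s
        gG += g_eta_s

        # CAR prior on the shared field
        Wg = self.W @ G
        quad = float(G @ (self.deg * G) - lam * (G @ Wg))
        logp += (-0.5 * nc * np.log(2.0 * np.pi)
                 + 0.5 * (nc * t + self.car.logdet_D
                          + float(np.sum(np.log1p(-lam * self.car.mu))))
                 - 0.5 * tau * quad)
        gG += -tau * (self.deg * G - lam * Wg)
        grad[self.i_g:] = gG

        # priors (with change-of-variable Jacobians)
        var = pr.beta_scale
        logp += (-0.5 * (np.sum(B * B) + np.sum(bs * bs)) / var
                 - 0.5 * (B.size + bs.size) * np.log(2.0 * np.pi * var))
        grad[: self.n_bp] += (-B / var).ravel()
        grad[self.i_bs:self.i_a] += -bs / var

        if self.n_free_a:
            af = alpha[self.free_alpha]
            aa, ab = pr.alpha_a, pr.alpha_b
            logp += float(np.sum(aa * np.log(af) + ab * np.log1p(-af)
                                 - betaln(aa, ab)))
            grad[self.i_a:self.i_l] = (
                g_alpha[self.free_alpha] * af * (1.0 - af)
                + aa * (1.0 - af) - ab * af)

        la, lb = pr.lambda_a, pr.lambda_b
        logp += (la * np.log(lam) + lb * np.log1p(-lam) - betaln(la, lb))
        dlam = (0.5 * self.car.dlogdet_dlambda(lam)
                + 0.5 * tau * float(G @ Wg))
        grad[self.i_l] = dlam * lam * (1.0 - lam) + la * (1.0 - lam) - lb * lam

        sh, sc = pr.tau_shape, pr.tau_scale
        logp += (sh * np.log(sc) - gammaln(sh) - sh * t - sc / tau)
        grad[self.i_t] = 0.5 * nc - 0.5 * tau * quad - sh + sc / tau

        if not np.isfinite(logp):
            return -np.inf, grad
        return float(logp), grad


@dataclass
class PosteriorSample:
    """Posterior draws with chain metadata and diagnostics.

    ``draws`` maps parameter names to arrays indexed
    (chain, draw, ...): ``beta_p`` (chain, draw, n_taxa, p_e),
    ``beta_s``, ``alpha``, ``lambda_g``, ``tau`` and the field ``g``
    (chain, draw, n_cells).  ``diagnostics`` holds per-parameter
    split-R-hat and effective sample sizes on the retained draws.
    """

    draws: dict
    config: FitConfig
    priors: Priors
    alpha_fixed: np.ndarray
    divergences: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["lambda_g"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["lambda_g"].shape[1]

    @property
    def converged(self) -> bool:
        """All non-field parameters have R-hat < 1.1."""
        return bool(self.max_rhat() < 1.1)

    def max_rhat(self, include_field: bool = False) -> float:
        names = [k for k in self.diagnostics["rhat"]
                 if include_field or k != "g"]
        return float(max(np.nanmax(np.atleast_1d(
            self.diagnostics["rhat"][k])) for k in names))

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` with chains stacked: (chain*draw, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def credible_interval(self, name: str, level: float = 0.95):
        """Equal-tailed credible interval(s), linear interpolation."""
        lo = 100.0 * (1.0 - level) / 2.0
        arr = self.stacked(name)
        return (np.percentile(arr, lo, axis=0),
                np.percentile(arr, 100.0 - lo, axis=0))

    # -- export --------------------------------------------------------
    def save(self, out_dir, include_field: bool = False):
        """Write draws.csv (parameter, chain, iteration, value),
        summary.csv (mean / CI / n_eff / R-hat per parameter) and
        diagnostics.json to a directory."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.draws_frame(include_field).to_csv(out / "draws.csv",
                                               index=False)
        summarize(self, include_field).to_csv(out / "summary.csv")
        diag = {
            "divergences": self.divergences.tolist(),
            "max_rhat": self.max_rhat(),
            "converged": self.converged,
            "rhat": {k: np.atleast_1d(v).tolist()
                     for k, v in self.diagnostics["rhat"].items()
                     if include_field or k != "g"},
            "ess": {k: np.atleast_1d(v).tolist()
                    for k, v in self.diagnostics["ess"].items()
                    if include_field or k != "g"},
        }
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2)

    def draws_frame(self, include_field: bool = False) -> pd.DataFrame:
        """Columnar draws: parameter, chain, iteration, value."""
        rows = []
        for name, labels, arr in _iter_scalars(self.draws, include_field):
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "parameter": name,
                    "chain": c,
                    "iteration": np.arange(arr.shape[1]),
                    "value": arr[c],
                }))
        return pd.concat(rows, ignore_index=True)


def _iter_scalars(draws: dict, include_field: bool):
    """Yield (label, key, (chain, draw) array) for every scalar."""
    for key, arr in draws.items():
        if key == "g" and not include_field:
            continue
        if arr.ndim == 2:
            yield key, key, arr
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            shape = arr.shape[2:]
            for j in range(flat.shape[2]):
                idx = np.unravel_index(j, shape)
                label = f"{key}[{','.join(map(str, idx))}]"
                yield label, key, flat[:, :, j]


def fit(data: ModelData, priors: Priors | None = None,
        fit_config: FitConfig | None = None,
        alpha_fixed=None, standardize: bool = False) -> PosteriorSample:
    """Sample the joint posterior by NUTS.

    Parameters
    ----------
    data : ModelData
    priors : Priors, optional (defaults: N(0, 100) coefficients,
        Beta(5, 5) mixture and spatial-dependence, Inv-Gamma(1, 0.01)
        precision)
    fit_config : FitConfig, optional
    alpha_fixed : array-like, optional
        Per-taxon fixed mixture weights; NaN entries are sampled.
        Fixing alpha_i = 1 reduces taxon i to a purely ecological
        spatial logistic regression.
    standardize : bool
        Z-score non-constant design columns before fitting.  Off by
        default so that coefficients keep the scale of the supplied
        covariates; turn on for raw (unscaled) covariates.

    Non-converged runs (R-hat >= 1.1 or divergent transitions) return
    the sample with a warning, never silently.
    """
    priors = priors or Priors()
    fit_config = fit_config or FitConfig()
    if standardize:
        data = data.standardize()
    post = _Posterior(data, priors, alpha_fixed=alpha_fixed)

    n_warm = fit_config.burn_in
    n_iter = fit_config.iterations - fit_config.burn_in
    seeds = np.random.SeedSequence(fit_config.seed).spawn(fit_config.chains)

    chains = []
    divergences = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        res = nuts(post.logp_grad, post.initial(rng), n_warm, n_iter, rng,
                   target_accept=fit_config.target_accept,
                   max_treedepth=fit_config.max_treedepth,
                   thin=fit_config.thinning)
        chains.append(res)
        divergences.append(res.divergences)

    k = min(c.draws.shape[0] for c in chains)
    theta = np.stack([c.draws[:k] for c in chains])  # (chains, k, dim)

    n, pe, ps, nc = post.n_taxa, post.pe, post.ps, post.n_cells
    nch = theta.shape[0]
    alpha = np.broadcast_to(post.alpha_fixed, (nch, k, n)).copy()
    alpha[..., post.free_alpha] = expit(
        theta[..., post.i_a:post.i_l])
    draws = {
        "beta_p": theta[..., : post.n_bp].reshape(nch, k, n, pe),
        "beta_s": theta[..., post.i_bs:post.i_a],
        "alpha": alpha,
        "lambda_g": expit(theta[..., post.i_l]),
        "tau": np.exp(theta[..., post.i_t]),
        "g": theta[..., post.i_g:],
    }

    sample = PosteriorSample(
        draws=draws, config=fit_config, priors=priors,
        alpha_fixed=post.alpha_fixed,
        divergences=np.array(divergences, dtype=int),
    )
    sample.diagnostics = _diagnostics(draws, post)
    if not sample.converged:
        warnings.warn(
            f"chains may not have converged: max R-hat = "
            f"{sample.max_rhat():.3f}", RuntimeWarning)
    if sample.divergences.sum() > 0:
        warnings.warn(
            f"{int(sample.divergences.sum())} divergent transition(s) "
            "after warmup", RuntimeWarning)
    return sample


def _diagnostics(draws: dict, post: _Posterior) -> dict:
    rh, ne = {}, {}
    for key, arr in draws.items():
        if key == "alpha" and post.n_free_a < post.n_taxa:
            free = post.free_alpha
            if not free.any():
                continue
            sub = arr[..., free]
            r = np.full(arr.shape[2], np.nan)
            e = np.full(arr.shape[2], np.nan)
            r[free] = np.atleast_1d(_rhat_array(sub))
            e[free] = np.atleast_1d(_ess_array(sub))
            rh[key], ne[key] = r, e
            continue
        rh[key] = _rhat_array(arr)
        ne[key] = _ess_array(arr)
    return {"rhat": rh, "ess": ne}


def _rhat_array(arr: np.ndarray):
    if arr.shape[0] < 2:
        return np.full(arr.shape[2:], np.nan) if arr.ndim > 2 else np.nan
    out = az.rhat(az.convert_to_dataset(arr))["x"].values
    return float(out) if out.ndim == 0 else out


def _ess_array(arr: np.ndarray):
    out = az.ess(az.convert_to_dataset(arr))["x"].values
    return float(out) if out.ndim == 0 else out


def rhat(draws: np.ndarray) -> float | np.ndarray:
    """Split-R-hat convergence diagnostic of a (chain, draw, ...) array.

    Uses the rank-normalized split statistic; values below 1.1 are
    taken as converged.  Constant chains yield NaN (the statistic's
    0/0 case), which is reported as-is.  At least two chains of at
    least four retained draws are required.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim < 2 or draws.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("rhat needs >= 4 draws per chain")
    return _rhat_array(draws)


def ess(draws: np.ndarray):
    """Effective sample size of a (chain, draw, ...) array."""
    return _ess_array(np.asarray(draws, dtype=float))


def summarize(posterior: PosteriorSample,
              include_field: bool = False) -> pd.DataFrame:
    """Posterior summary table.

    One row per scalar parameter: mean, 2.5% / 50% / 97.5% percentiles
    (linear interpolation), effective sample size, R-hat, and a
    significance flag set when the central 95% interval excludes zero.
    """
    rows = []
    diag = posterior.diagnostics

    def lookup(table, key, label):
        if key not in table:
            return np.nan
        val = np.atleast_1d(np.asarray(table[key], dtype=float))
        if label == key:
            return float(val.ravel()[0])
        idx = tuple(int(v)
                    for v in label[label.index("[") + 1:-1].split(","))
        return float(val.reshape(posterior.draws[key].shape[2:])[idx])

    for label, key, arr in _iter_scalars(posterior.draws, include_field):
        flat = arr.reshape(-1)
        lo, med, hi = np.percentile(flat, [2.5, 50.0, 97.5])
        rows.append({
            "parameter": label, "mean": float(flat.mean()),
            "2.5%": lo, "50%": med, "97.5%": hi,
            "n_eff": lookup(diag["ess"], key, label),
            "r_hat": lookup(diag["rhat"], key, label),
            "significant": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows).set_index("parameter")


def latent_process_draws(posterior: PosteriorSample, data: ModelData,
                         cells=None):
    """Per-draw latent probabilities (P_i, S, Q_i) at selected cells.

    Returns (P, S, Q) with shapes (draws, n_taxa, m), (draws, m) and
    (draws, n_taxa, m) where m = len(cells) (all cells by default).
    Draws are pooled across chains.
    """
    if cells is None:
        cells = np.arange(data.n_cells)
    cells = np.asarray(cells, dtype=int)
    B = posterior.stacked("beta_p")      # (d, n, pe)
    bs = posterior.stacked("beta_s")     # (d, ps)
    alpha = posterior.stacked("alpha")   # (d, n)
    G = posterior.stacked("g")[:, cells]  # (d, m)
    S = expit(bs @ data.design_samp[cells].T + G)
    P = np.empty((B.shape[0], data.n_taxa, cells.size))
    for i in range(data.n_taxa):
        De = data.design_eco_for(i)[cells]
        P[:, i, :] = expit(B[:, i, :] @ De.T + G)
    Q = alpha[:, :, None] * P + (1.0 - alpha[:, :, None]) * S[:, None, :]
    return P, S, Q


def impute_missing(posterior: PosteriorSample,
                   data: ModelData) -> pd.DataFrame:
    """Posterior presence probabilities at missing cells.

    For each missing cell the relevant per-draw latent probability
    (Q_i for a taxon response, S for the complementary response) is
    averaged over the posterior draws; the shared field makes these
    probabilities borrow strength from neighbouring observed cells.
    Returns a DataFrame with columns ``response`` ("y0", ..., "y_c"),
    ``cell`` (0-based position) and ``prob``; empty if nothing is
    missing.
    """
    rows = []
    miss_any = [np.nonzero(data.y[i] == MISSING)[0]
                for i in range(data.n_taxa)]
    miss_c = np.nonzero(data.y_c == MISSING)[0]
    all_cells = np.unique(np.concatenate([*miss_any, miss_c])) \
        if (miss_c.size or any(m.size for m in miss_any)) else np.array([], int)
    if all_cells.size == 0:
        return pd.DataFrame(columns=["response", "cell", "prob"])
    pos = {int(c): j for j, c in enumerate(all_cells)}
    _, S, Q = latent_process_draws(posterior, data, cells=all_cells)
    for i in range(data.n_taxa):
        for c in miss_any[i]:
            rows.append({"response": f"y{i}", "cell": int(c),
                         "prob": float(Q[:, i, pos[int(c)]].mean())})
    for c in miss_c:
        rows.append({"response": "y_c", "cell": int(c),
                     "prob": float(S[:, pos[int(c)]].mean())})
    return pd.DataFrame(rows)
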