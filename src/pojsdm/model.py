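"""Mathematical core: CAR density, logistic processes, mixture, posterior.

The model.  Each cell x_k of a lattice carries a shared Gaussian field
G(x_k) with a proper conditional autoregressive (CAR) prior,

    G ~ N(0, Q^{-1}),    Q = tau * (D - lambda_G * W),

where W is the binary adjacency matrix, D the diagonal degree matrix,
lambda_G in (0, 1) the spatial-dependence parameter and tau > 0 a
precision multiplier (the field's overall variance is of order 1/tau).
Each taxon i has an ecological-suitability process

    logit P_i(x_k) = beta_pi' d_e(x_k) + G(x_k),

all taxa share one sampling-effort process

    logit S(x_k)   = beta_s' d_a(x_k) + G(x_k),

and the observation probability is the convex mixture

    Q_i(x_k) = alpha_i * P_i(x_k) + (1 - alpha_i) * S(x_k),

with alpha_i in [0, 1] the taxon's contribution to ecological
suitability (1 - alpha_i is the sampling-bias share).  Observed taxon
responses y_i and the complementary response y^c are Bernoulli at Q_i
and S respectively; missing cells contribute no observation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.special import expit, betaln, gammaln

from .lattice import Adjacency, CellResponse, MISSING

__all__ = [
    "ModelData", "ModelParams", "Priors", "CarStructure",
    "car_precision", "car_logpdf", "process_probability",
    "mixture_probability", "joint_log_posterior",
]


# --------------------------------------------------------------------------
# Proper CAR
# --------------------------------------------------------------------------

class CarStructure:
    """Cached spectral decomposition for a proper CAR precision.

    Writing D - lambda*W = D^{1/2} (I - lambda * M) D^{1/2} with
    M = D^{-1/2} W D^{-1/2}, the log-determinant and its derivative in
    lambda reduce to sums over the (once-computed) eigenvalues of M.
    On a connected lattice the eigenvalues of M lie in [-1, 1] with
    max exactly 1, so D - lambda*W is positive definite for every
    lambda in (0, 1).
    """

    def __init__(self, adjacency: Adjacency):
        self.adjacency = adjacency
        self.W = sp.csr_matrix(adjacency.matrix, dtype=float)
        self.degrees = np.asarray(adjacency.degrees, dtype=float)
        if np.any(self.degrees <= 0):
            raise ValueError(
                "CAR precision is singular: lattice has isolated cells "
                "(degree 0)")
        self.n = self.degrees.size
        d_isqrt = 1.0 / np.sqrt(self.degrees)
        M = (self.W.multiply(d_isqrt[:, None])).multiply(d_isqrt[None, :])
        self.mu = np.linalg.eigvalsh(M.toarray())
        self.logdet_D = float(np.sum(np.log(self.degrees)))

    def check_lambda(self, lambda_g: float):
        if not (0.0 < lambda_g < 1.0):
            raise ValueError("lambda_G must lie strictly in (0, 1)")
        if np.any(1.0 - lambda_g * self.mu <= 0):
            raise ValueError(
                "CAR precision not positive definite at "
                f"lambda_G={lambda_g}")

    def logdet(self, lambda_g: float, tau: float) -> float:
        """log |tau * (D - lambda*W)|."""
        self.check_lambda(lambda_g)
        return (self.n * np.log(tau) + self.logdet_D
                + float(np.sum(np.log1p(-lambda_g * self.mu))))

    def dlogdet_dlambda(self, lambda_g: float) -> float:
        return -float(np.sum(self.mu / (1.0 - lambda_g * self.mu)))

    def quad(self, g: np.ndarray, lambda_g: float) -> float:
        """g' (D - lambda*W) g."""
        return float(g @ (self.degrees * g) - lambda_g * (g @ (self.W @ g)))

    def logpdf(self, g: np.ndarray, lambda_g: float, tau: float) -> float:
        g = np.asarray(g, dtype=float)
        if g.size != self.n:
            raise ValueError("field length does not match lattice size")
        if tau <= 0:
            raise ValueError("tau must be positive")
        return (-0.5 * self.n * np.log(2.0 * np.pi)
                + 0.5 * self.logdet(lambda_g, tau)
                - 0.5 * tau * self.quad(g, lambda_g))


def car_precision(adjacency: Adjacency, lambda_g: float,
                  tau: float) -> sp.csr_matrix:
    """Proper-CAR precision Q = tau * (D - lambda_G * W), sparse.

    Positive definite for lambda_G in (0, 1) on lattices without
    isolated cells.
    """
    if not (0.0 < lambda_g < 1.0):
        raise ValueError("lambda_G must lie strictly in (0, 1)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    W = sp.csr_matrix(adjacency.matrix, dtype=float)
    D = sp.diags(np.asarray(adjacency.degrees, dtype=float))
    return sp.csr_matrix(tau * (D - lambda_g * W))


def car_logpdf(g, adjacency: Adjacency, lambda_g: float, tau: float,
               structure: CarStructure | None = None) -> float:
    """Log-density of the zero-mean proper-CAR field.

    Equals the dense multivariate-normal log-density with covariance
    Q^{-1}; evaluated via the cached spectral form (no dense inverse).
    Pass a :class:`CarStructure` to reuse the decomposition.
    """
    if structure is None:
        structure = CarStructure(adjacency)
    return structure.logpdf(np.asarray(g, dtype=float), lambda_g, tau)


# --------------------------------------------------------------------------
# Processes and mixture
# --------------------------------------------------------------------------

def process_probability(design, beta, g):
    """Logistic process probability logit^{-1}(design @ beta + g).

    Used identically for every ecological process P_i (ecological
    design, beta_pi) and for the sampling effort S (anthropological
    design, beta_s); ``g`` is the same shared field in both.
    Accepts a single row or a full (n_cells, p) design matrix.
    """
    design = np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if design.shape[-1] != beta.shape[0]:
        raise ValueError(
            f"design has {design.shape[-1]} columns but beta has "
            f"{beta.shape[0]} entries")
    return expit(design @ beta + np.asarray(g, dtype=float))


def mixture_probability(p, s, alpha):
    """Convex mixture q = alpha * p + (1 - alpha) * s on the
    probability scale."""
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(s < 0) or np.any(s > 1):
        raise ValueError("p and s must be probabilities")
    if np.any(np.asarray(alpha) < 0) or np.any(np.asarray(alpha) > 1):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * p + (1.0 - alpha) * s


# --------------------------------------------------------------------------
# Data / parameter / prior containers
# --------------------------------------------------------------------------

@dataclass
class ModelData:
    """Responses and design matrices on a common lattice.

    Attributes
    ----------
    y : (n_taxa, n_cells) int8 array
        Taxon responses; entries 1 (present), 0 (absent) or
        :data:`MISSING`.
    y_c : (n_cells,) int8 array
        Complementary response with the same encoding.
    design_eco : (n_cells, r+1) array or list of such, per taxon
        Ecological design matrix/matrices, intercept column first.
        A single array is shared by all taxa (the default layout).
    design_samp : (n_cells, s+1) array
        Anthropological (sampling-effort) design matrix, intercept
        column first.
    adjacency : Adjacency
    cell_ids : sequence of str, optional
    """

    y: np.ndarray
    y_c: np.ndarray
    design_eco: object
    design_samp: np.ndarray
    adjacency: Adjacency
    cell_ids: tuple = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim == 1:
            self.y = self.y[None, :]
        self.y_c = np.asarray(self.y_c, dtype=np.int8)
        self.design_samp = np.asarray(self.design_samp, dtype=float)
        if isinstance(self.design_eco, (list, tuple)):
            self.design_eco = [np.asarray(d, dtype=float)
                               for d in self.design_eco]
        else:
            self.design_eco = np.asarray(self.design_eco, dtype=float)
        self.validate()

    # -- dimensions ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.y.shape[0]

    @property
    def n_cells(self) -> int:
        return self.y.shape[1]

    def design_eco_for(self, i: int) -> np.ndarray:
        if isinstance(self.design_eco, list):
            return self.design_eco[i]
        return self.design_eco

    @property
    def p_eco(self) -> int:
        return self.design_eco_for(0).shape[1]

    @property
    def p_samp(self) -> int:
        return self.design_samp.shape[1]

    def validate(self):
        n = self.n_cells
        if self.y_c.shape != (n,):
            raise ValueError("y_c length does not match y's cell count")
        for arr in (self.y, self.y_c[None, :]):
            if not np.isin(arr, [0, 1, MISSING]).all():
                raise ValueError("responses must be 0, 1 or MISSING")
        for i in range(self.n_taxa):
            d = self.design_eco_for(i)
            if d.shape[0] != n:
                raise ValueError("ecological design rows != n_cells")
            if np.isnan(d).any():
                raise ValueError("ecological design contains NaN")
        if self.design_samp.shape[0] != n:
            raise ValueError("sampling design rows != n_cells")
        if np.isnan(self.design_samp).any():
            raise ValueError("sampling design contains NaN")
        if self.adjacency is not None and self.adjacency.n_cells != n:
            raise ValueError("adjacency size does not match n_cells")

    def standardize(self) -> "ModelData":
        """Z-score all non-constant design columns (new ModelData).

        Constant (intercept) columns are left untouched.  Recommended
        with the wide default priors.
        """
        def z(mat):
            mat = mat.copy()
            sd = mat.std(axis=0)
            varying = sd > 0
            mat[:, varying] = ((mat[:, varying] - mat[:, varying].mean(axis=0))
                               / sd[varying])
            return mat

        eco = ([z(d) for d in self.design_eco]
               if isinstance(self.design_eco, list) else z(self.design_eco))
        return ModelData(y=self.y.copy(), y_c=self.y_c.copy(),
                         design_eco=eco, design_samp=z(self.design_samp),
                         adjacency=self.adjacency, cell_ids=self.cell_ids)

    def responses(self):
        """Taxon responses as CellResponse objects (convenience)."""
        return [CellResponse(values=self.y[i]) for i in range(self.n_taxa)]


@dataclass
class ModelParams:
    """One full parameter state of the model.

    ``beta_p`` is (n_taxa, r+1) with the intercept first, ``beta_s``
    is (s+1,), ``alpha`` has one entry in [0, 1] per taxon,
    ``lambda_g`` lies in (0, 1), ``tau`` is a positive precision and
    ``g`` is the shared per-cell field.
    """

    beta_p: np.ndarray
    beta_s: np.ndarray
    alpha: np.ndarray
    lambda_g: float
    tau: float
    g: np.ndarray

    def __post_init__(self):
        self.beta_p = np.atleast_2d(np.asarray(self.beta_p, dtype=float))
        self.beta_s = np.asarray(self.beta_s, dtype=float)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.alpha < 0) or np.any(self.alpha > 1):
            raise ValueError("alpha entries must lie in [0, 1]")
        if not (0.0 < self.lambda_g < 1.0):
            raise ValueError("lambda_g must lie strictly in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class Priors:
    """Prior hyperparameters.

    beta_scale is the *variance* of the zero-mean normal priors on all
    regression coefficients (default 100, matching standardized
    covariates; use 1e4 for raw covariates).  alpha and lambda_G have
    Beta priors (default Beta(5, 5)); tau has an inverse-gamma prior
    (default Inv-Gamma(1, 0.01)).
    """

    beta_scale: float = 100.0
    alpha_a: float = 5.0
    alpha_b: float = 5.0
    lambda_a: float = 5.0
    lambda_b: float = 5.0
    tau_shape: float = 1.0
    tau_scale: float = 0.01

    def __post_init__(self):
        vals = [self.beta_scale, self.alpha_a, self.alpha_b,
                self.lambda_a, self.lambda_b, self.tau_shape,
                self.tau_scale]
        if any(v <= 0 for v in vals):
            raise ValueError("all prior hyperparameters must be positive")

    def to_json(self, path=None):
        import dataclasses
        import json

        obj = dataclasses.asdict(self)
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
        return None

    @classmethod
    def from_json(cls, path_or_str) -> "Priors":
        import json

        try:
            obj = json.loads(path_or_str)
        except (ValueError, TypeError):
            with open(path_or_str) as fh:
                obj = json.load(fh)
        return cls(**obj)


# --------------------------------------------------------------------------
# Joint log-posterior
# --------------------------------------------------------------------------

def _bernoulli_loglik(y: np.ndarray, prob: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihoods over observed cells.

    Missing cells (y == MISSING) contribute nothing.  A probability of
    exactly 0 or 1 conflicting with an observation yields -inf (no
    exception).
    """
    obs = y != MISSING
    if not obs.any():
        return 0.0
    yo = y[obs].astype(float)
    po = np.asarray(prob, dtype=float)[obs]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = yo * np.log(po) + (1.0 - yo) * np.log1p(-po)
    # 0 * log 0 -> nan; an observation matching a degenerate
    # probability carries zero information, not -inf
    terms = np.where((yo == 1.0) & (po == 1.0), 0.0, terms)
    terms = np.where((yo == 0.0) & (po == 0.0), 0.0, terms)
    if np.isnan(terms).any():
        return -np.inf
    return float(terms.sum())


def joint_log_posterior(params: ModelParams, data: ModelData,
                        priors: Priors,
                        structure: CarStructure | None = None) -> float:
    """Joint log-posterior density, up to an additive constant.

    Sums the Bernoulli log-likelihoods of the observed taxon responses
    at their mixture probabilities Q_i, the Bernoulli log-likelihood of
    the observed complementary response at S, the proper-CAR log-density
    of the shared field, and the log-priors on beta_p, beta_s, alpha,
    lambda_G and tau.  Cells with missing responses contribute no
    observation term (their Bernoulli factor is marginalized exactly).

    This is the readable reference implementation; the sampler uses an
    algebraically identical fused version with analytic gradients.
    """
    if params.beta_p.shape[0] != data.n_taxa:
        raise ValueError("beta_p rows != n_taxa")
    if params.alpha.shape[0] != data.n_taxa:
        raise ValueError("alpha length != n_taxa")
    if structure is None:
        structure = CarStructure(data.adjacency)

    s_field = process_probability(data.design_samp, params.beta_s, params.g)
    total = _bernoulli_loglik(data.y_c, s_field)
    for i in range(data.n_taxa):
        p_i = process_probability(data.design_eco_for(i),
                                  params.beta_p[i], params.g)
        q_i = mixture_probability(p_i, s_field, params.alpha[i])
        total += _bernoulli_loglik(data.y[i], q_i)
    if not np.isfinite(total):
        return -np.inf

    total += structure.logpdf(params.g, params.lambda_g, params.tau)

    # log-priors
    var = priors.beta_scale
    n_beta = params.beta_p.size + params.beta_s.size
    total += (-0.5 * (np.sum(params.beta_p ** 2)
                      + np.sum(params.beta_s ** 2)) / var
              - 0.5 * n_beta * np.log(2.0 * np.pi * var))
    def beta_logpdf(x, a, b):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        with np.errstate(divide="ignore"):
            t1 = (np.zeros_like(x) if a == 1.0
                  else (a - 1.0) * np.log(x))
            t2 = (np.zeros_like(x) if b == 1.0
                  else (b - 1.0) * np.log1p(-x))
        return float(np.sum(t1 + t2 - betaln(a, b)))

    total += beta_logpdf(params.alpha, priors.alpha_a, priors.alpha_b)
    total += beta_logpdf(params.lambda_g, priors.lambda_a, priors.lambda_b)
    sh, sc = priors.tau_shape, priors.tau_scale
    total += (sh * np.log(sc) - gammaln(sh)
              - (sh + 1.0) * np.log(params.tau) - sc / params.tau)
    if np.isnan(total):
        return -np.inf
    return float(total)
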