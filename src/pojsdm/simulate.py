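"""Generative simulation from the model's own specification.

The simulator draws a CAR field on a grid lattice, builds logistic
ecological and sampling-effort probabilities from Gaussian covariates,
combines them by the per-taxon convex mixture, samples Bernoulli
responses and optionally masks a fraction of cells as missing.  The
defaults are the package's stated validation world: a 25 x 25 rook
lattice, three taxa with mixture weights (0.8, 0.5, 0.2), two
ecological and two anthropological covariates, lambda_G = 0.9 and
tau = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .lattice import (Lattice, Adjacency, CellResponse, MISSING,
                      build_grid_lattice, adjacency_from_lattice)
from .model import (ModelData, ModelParams, Priors, car_precision,
                    process_probability, mixture_probability)

__all__ = [
    "SimulationTruth", "default_params", "simulate_car_field",
    "simulate_covariates", "simulate_dataset", "save_simulation",
    "load_simulation",
]

#: stated-world generating coefficients (intercept first) for up to
#: three taxa; chosen once to give moderate, spatially varying
#: occupancy on standardized covariates
DEFAULT_BETA_P = np.array([
    [0.5, 1.0, -1.0],
    [-0.5, 1.5, 0.5],
    [0.0, -1.0, 1.0],
])
DEFAULT_BETA_S = np.array([0.5, 1.0, -0.5])
DEFAULT_ALPHA = np.array([0.8, 0.5, 0.2])
DEFAULT_LAMBDA_G = 0.9
DEFAULT_TAU = 1.0


@dataclass
class SimulationTruth:
    """A simulated dataset together with everything that generated it."""

    params: ModelParams
    data: ModelData
    lattice: Lattice
    latent_p: np.ndarray  # (n_taxa, n_cells) true P_i
    latent_s: np.ndarray  # (n_cells,) true S
    latent_q: np.ndarray  # (n_taxa, n_cells) true Q_i
    seed: int


def simulate_car_field(adjacency: Adjacency, lambda_g: float, tau: float,
                       rng) -> np.ndarray:
    """Exact draw from the proper-CAR prior N(0, Q^{-1}).

    Draws z ~ N(0, I) and solves L' g = z with Q = L L' (Cholesky), so
    g has covariance Q^{-1} exactly.
    """
    rng = np.random.default_rng(rng)
    Q = car_precision(adjacency, lambda_g, tau).toarray()
    L = scipy.linalg.cholesky(Q, lower=True)
    z = rng.standard_normal(Q.shape[0])
    return scipy.linalg.solve_triangular(L, z, lower=True, trans="T")


def simulate_covariates(n_cells: int, r: int, s: int, rng,
                        adjacency: Adjacency | None = None,
                        smoothing: int = 0):
    """Standard-normal covariate columns plus intercepts.

    Returns (D_e, D_a) with shapes (n_cells, r+1) and (n_cells, s+1),
    intercept column first.  With ``smoothing`` > 0 each column is
    replaced ``smoothing`` times by the average of itself and its
    lattice neighbours (then re-standardized), which induces positive
    spatial autocorrelation; 0 leaves columns spatially white.
    """
    if r < 1 or s < 1:
        raise ValueError("r and s must be >= 1")
    rng = np.random.default_rng(rng)

    def columns(k):
        cols = rng.standard_normal((n_cells, k))
        if smoothing > 0:
            if adjacency is None:
                raise ValueError("smoothing requires an adjacency")
            W = adjacency.matrix.astype(float)
            deg = np.asarray(adjacency.degrees, dtype=float)
            for _ in range(smoothing):
                cols = (cols + (W @ cols)) / (1.0 + deg)[:, None]
            cols = (cols - cols.mean(axis=0)) / cols.std(axis=0)
        return np.column_stack([np.ones(n_cells), cols])

    return columns(r), columns(s)


def default_params(n_taxa: int, r: int, s: int,
                   n_cells: int) -> ModelParams:
    """The stated-world generating parameters (placeholder zero field)."""
    if n_taxa > DEFAULT_BETA_P.shape[0] or r + 1 > DEFAULT_BETA_P.shape[1] \
            or s + 1 > DEFAULT_BETA_S.shape[0]:
        raise ValueError(
            "no stated default parameters at this size; pass params=")
    return ModelParams(
        beta_p=DEFAULT_BETA_P[:n_taxa, : r + 1].copy(),
        beta_s=DEFAULT_BETA_S[: s + 1].copy(),
        alpha=DEFAULT_ALPHA[:n_taxa].copy(),
        lambda_g=DEFAULT_LAMBDA_G,
        tau=DEFAULT_TAU,
        g=np.zeros(n_cells),
    )


def draw_params_from_priors(priors: Priors, n_taxa: int, r: int, s: int,
                            n_cells: int, rng) -> ModelParams:
    """Draw generating parameters from the prior (placeholder field).

    Used for coverage calibration, where the generating distribution
    must equal the fitting prior.
    """
    rng = np.random.default_rng(rng)
    sd = np.sqrt(priors.beta_scale)
    return ModelParams(
        beta_p=rng.normal(0.0, sd, size=(n_taxa, r + 1)),
        beta_s=rng.normal(0.0, sd, size=s + 1),
        alpha=rng.beta(priors.alpha_a, priors.alpha_b, size=n_taxa),
        lambda_g=float(rng.beta(priors.lambda_a, priors.lambda_b)),
        tau=float(1.0 / rng.gamma(priors.tau_shape,
                                  1.0 / priors.tau_scale)),
        g=np.zeros(n_cells),
    )


def simulate_dataset(n_taxa: int = 3, nx: int = 25, ny: int = 25,
                     r: int = 2, s: int = 2,
                     params: ModelParams | None = None,
                     priors: Priors | None = None,
                     missing_fraction: float = 0.0,
                     missing_y_fraction: float = 0.0,
                     covariate_smoothing: int = 0,
                     adjacency_rule: str = "rook",
                     seed: int = 0) -> SimulationTruth:
    """Simulate a dataset from the generative model.

    Draws the shared CAR field, computes P_i, S and the mixtures Q_i,
    samples y_i ~ Bernoulli(Q_i) and y^c ~ Bernoulli(S), then masks a
    ``missing_fraction`` of y^c cells (and ``missing_y_fraction`` of
    each taxon's cells) completely at random as missing.

    If ``priors`` is given the generating parameters are drawn from it
    (for coverage studies); otherwise ``params`` or the stated-world
    defaults are used.  The result is bit-reproducible for a given
    seed and configuration.
    """
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must lie in [0, 1)")
    if not (0.0 <= missing_y_fraction < 1.0):
        raise ValueError("missing_y_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lattice = build_grid_lattice((0.0, 0.0, float(nx), float(ny)), 1.0)
    adjacency = adjacency_from_lattice(lattice, adjacency_rule)
    n_cells = lattice.n_cells

    if priors is not None:
        params = draw_params_from_priors(priors, n_taxa, r, s, n_cells, rng)
    elif params is None:
        params = default_params(n_taxa, r, s, n_cells)

    d_e, d_a = simulate_covariates(n_cells, r, s, rng,
                                   adjacency=adjacency,
                                   smoothing=covariate_smoothing)
    g = simulate_car_field(adjacency, params.lambda_g, params.tau, rng)
    params = ModelParams(beta_p=params.beta_p, beta_s=params.beta_s,
                         alpha=params.alpha, lambda_g=params.lambda_g,
                         tau=params.tau, g=g)

    latent_s = process_probability(d_a, params.beta_s, g)
    latent_p = np.stack([
        process_probability(d_e, params.beta_p[i], g)
        for i in range(n_taxa)
    ])
    latent_q = np.stack([
        mixture_probability(latent_p[i], latent_s, params.alpha[i])
        for i in range(n_taxa)
    ])

    y = (rng.random((n_taxa, n_cells)) < latent_q).astype(np.int8)
    y_c = (rng.random(n_cells) < latent_s).astype(np.int8)

    if missing_fraction > 0:
        k = int(round(missing_fraction * n_cells))
        idx = rng.choice(n_cells, size=k, replace=False)
        y_c[idx] = MISSING
    if missing_y_fraction > 0:
        k = int(round(missing_y_fraction * n_cells))
        for i in range(n_taxa):
            idx = rng.choice(n_cells, size=k, replace=False)
            y[i, idx] = MISSING

    data = ModelData(y=y, y_c=y_c, design_eco=d_e, design_samp=d_a,
                     adjacency=adjacency, cell_ids=lattice.cell_ids)
    return SimulationTruth(params=params, data=data, lattice=lattice,
                           latent_p=latent_p, latent_s=latent_s,
                           latent_q=latent_q, seed=int(seed))


# --------------------------------------------------------------------------
# Directory export / import
# --------------------------------------------------------------------------

def save_simulation(truth: SimulationTruth, out_dir):
    """Write a SimulationTruth to a directory of plain-text files.

    Layout: responses.csv (per-cell y_i and y^c, missing as empty
    field), design_eco.csv, design_samp.csv, adjacency.mtx (pattern),
    lattice.geojson, truth.json (parameters, latent fields, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, lattice = truth.data, truth.lattice

    cols = {"cell_id": list(lattice.cell_ids)}
    for i in range(data.n_taxa):
        cols[f"y{i}"] = [("" if v == MISSING else int(v))
                         for v in data.y[i]]
    cols["y_c"] = [("" if v == MISSING else int(v)) for v in data.y_c]
    pd.DataFrame(cols).to_csv(out / "responses.csv", index=False)

    d_e = data.design_eco_for(0)
    pd.DataFrame(d_e, columns=[f"e{j}" for j in range(d_e.shape[1])]) \
        .assign(cell_id=list(lattice.cell_ids)) \
        .to_csv(out / "design_eco.csv", index=False)
    pd.DataFrame(data.design_samp,
                 columns=[f"a{j}" for j in range(data.design_samp.shape[1])]) \
        .assign(cell_id=list(lattice.cell_ids)) \
        .to_csv(out / "design_samp.csv", index=False)

    data.adjacency.to_mtx(out / "adjacency.mtx")
    lattice.to_geojson(out / "lattice.geojson")

    with open(out / "truth.json", "w") as fh:
        json.dump({
            "seed": truth.seed,
            "beta_p": truth.params.beta_p.tolist(),
            "beta_s": truth.params.beta_s.tolist(),
            "alpha": truth.params.alpha.tolist(),
            "lambda_g": truth.params.lambda_g,
            "tau": truth.params.tau,
            "g": truth.params.g.tolist(),
            "latent_p": truth.latent_p.tolist(),
            "latent_s": truth.latent_s.tolist(),
            "latent_q": truth.latent_q.tolist(),
        }, fh)


def load_simulation(in_dir) -> SimulationTruth:
    """Inverse of :func:`save_simulation` (lossless round-trip)."""
    src = Path(in_dir)
    lattice = Lattice.from_geojson(src / "lattice.geojson")
    adjacency = Adjacency.from_mtx(src / "adjacency.mtx")

    resp = pd.read_csv(src / "responses.csv", dtype={"cell_id": str})
    taxa_cols = [c for c in resp.columns if c.startswith("y")
                 and c != "y_c"]
    def col(name):
        raw = resp[name].to_numpy()
        vals = np.full(len(resp), MISSING, dtype=np.int8)
        ok = ~pd.isna(raw)
        vals[ok] = np.asarray(raw[ok], dtype=float).astype(np.int8)
        return vals

    y = np.stack([col(c) for c in taxa_cols])
    y_c = col("y_c")
    d_e = pd.read_csv(src / "design_eco.csv") \
        .drop(columns=["cell_id"]).to_numpy(dtype=float)
    d_a = pd.read_csv(src / "design_samp.csv") \
        .drop(columns=["cell_id"]).to_numpy(dtype=float)

    with open(src / "truth.json") as fh:
        t = json.load(fh)
    params = ModelParams(beta_p=np.array(t["beta_p"]),
                         beta_s=np.array(t["beta_s"]),
                         alpha=np.array(t["alpha"]),
                         lambda_g=t["lambda_g"], tau=t["tau"],
                         g=np.array(t["g"]))
    data = ModelData(y=y, y_c=y_c, design_eco=d_e, design_samp=d_a,
                     adjacency=adjacency, cell_ids=lattice.cell_ids)
    return SimulationTruth(params=params, data=data, lattice=lattice,
                           latent_p=np.array(t["latent_p"]),
                           latent_s=np.array(t["latent_s"]),
                           latent_q=np.array(t["latent_q"]),
                           seed=int(t["seed"]))
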