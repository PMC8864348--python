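"""Posterior maps and cross-validated predictive performance.

Posterior maps average the *per-draw* latent probabilities P_i, S and
Q_i over the posterior — the mixture map is reconstructed jointly from
each draw's (alpha_i, P_i, S), never from averaged components, since
the mean of the mixture is not the mixture of the means.

Predictive performance is measured by k-fold cross-validation at the
cell level: each fold's responses are masked as missing, the model is
refit, and the held-out cells are scored by their imputed posterior
probabilities (Q_i for taxon responses, S for the complementary
response) against the held-out 0/1 labels via ROC/AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .lattice import MISSING, Lattice
from .model import ModelData, Priors
from .inference import (FitConfig, PosteriorSample, fit,
                        latent_process_draws)

__all__ = ["CellPosteriorMap", "CVResult", "posterior_maps",
           "rank_auc", "trapezoid_auc", "kfold_auc",
           "maps_to_csv", "maps_to_geojson"]


@dataclass
class CellPosteriorMap:
    """Per-cell posterior mean (and 95% interval) of one process."""

    process: str          # "P", "S" or "Q"
    taxon: int | None     # None for the shared sampling effort S
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    @property
    def label(self) -> str:
        return self.process if self.taxon is None \
            else f"{self.process}{self.taxon}"


def posterior_maps(posterior: PosteriorSample,
                   data: ModelData) -> list:
    """Posterior mean maps of P_i, S and Q_i for every taxon.

    Each map averages the per-draw cell probabilities; the credible
    band is the equal-tailed 95% interval of those draws.
    """
    P, S, Q = latent_process_draws(posterior, data)
    out = []
    for i in range(data.n_taxa):
        for name, arr in (("P", P[:, i, :]), ("Q", Q[:, i, :])):
            lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            out.append(CellPosteriorMap(process=name, taxon=i,
                                        mean=arr.mean(axis=0),
                                        lo95=lo, hi95=hi))
    lo, hi = np.percentile(S, [2.5, 97.5], axis=0)
    out.append(CellPosteriorMap(process="S", taxon=None,
                                mean=S.mean(axis=0), lo95=lo, hi95=hi))
    return out


# --------------------------------------------------------------------------
# AUC, two routes
# --------------------------------------------------------------------------

def rank_auc(labels, scores) -> float:
    """AUC via the Mann-Whitney rank statistic (ties: average ranks).

    NaN when the labels are single-class.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0)
                 / (n1 * n0))


def trapezoid_auc(labels, scores):
    """AUC by trapezoidal integration of the ROC curve.

    Returns (auc, fpr, tpr).  Agrees with :func:`rank_auc` to
    floating-point precision (average ranks correspond to the diagonal
    segments the trapezoid rule draws through ties).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels[~np.isnan(np.asarray(scores, float))])) < 2:
        return float("nan"), np.array([]), np.array([])
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


# --------------------------------------------------------------------------
# k-fold cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Cross-validation outcome.

    ``table`` has one row per (fold, response) with the held-out AUC
    (NaN for single-class folds).  ``pooled_auc`` pools all held-out
    (label, score) pairs across folds and responses; ``auc_range`` is
    the (min, max) of the per-fold pooled AUCs.
    """

    k: int
    seed: int
    fold_of_cell: np.ndarray
    table: pd.DataFrame
    per_taxon_auc: dict
    pooled_auc: float
    auc_range: tuple
    roc: tuple  # pooled (fpr, tpr)

    def to_json(self, path=None):
        obj = {"k": self.k, "seed": self.seed,
               "pooled_auc": self.pooled_auc,
               "auc_range": list(self.auc_range),
               "per_taxon_auc": {str(k): v
                                 for k, v in self.per_taxon_auc.items()}}
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
        return None


def make_folds(labels: np.ndarray, k: int, rng) -> np.ndarray:
    """Stratified fold assignment: a permutation within each class is
    dealt round-robin, so class ratios are preserved up to one cell."""
    labels = np.asarray(labels)
    folds = np.full(labels.size, -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def kfold_auc(data: ModelData, priors: Priors | None = None,
              fit_config: FitConfig | None = None, k: int = 5,
              seed: int = 0,
              include_complementary: bool = True) -> CVResult:
    """k-fold cross-validated ROC/AUC on held-out cells.

    Cells are partitioned into k stratified folds (stratum: whether
    any taxon is present in the cell).  For each fold all responses at
    the fold's cells are masked as missing, the model is refit, and
    every originally observed (response, cell) pair in the fold is
    scored by its imputed posterior probability.  Only originally
    observed responses are ever scored.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    observed_any = (data.y != MISSING).any(axis=0) | (data.y_c != MISSING)
    strata = (data.y == 1).any(axis=0).astype(int)
    folds = np.full(data.n_cells, -1, dtype=int)
    eligible = np.nonzero(observed_any)[0]
    folds[eligible] = make_folds(strata[eligible], k, rng)

    responses = [f"y{i}" for i in range(data.n_taxa)]
    if include_complementary:
        responses.append("y_c")

    rows = []
    pooled = {resp: ([], []) for resp in responses}
    fold_pooled = []
    for f in range(k):
        mask = folds == f
        y = data.y.copy()
        y_c = data.y_c.copy()
        held = {f"y{i}": np.nonzero(mask & (data.y[i] != MISSING))[0]
                for i in range(data.n_taxa)}
        held["y_c"] = np.nonzero(mask & (data.y_c != MISSING))[0]
        y[:, mask] = MISSING
        y_c[mask] = MISSING
        fold_data = ModelData(y=y, y_c=y_c, design_eco=data.design_eco,
                              design_samp=data.design_samp,
                              adjacency=data.adjacency,
                              cell_ids=data.cell_ids)
        cfg = fit_config or FitConfig()
        cfg = replace(cfg, seed=cfg.seed + 1000 * (f + 1))
        posterior = fit(fold_data, priors, cfg)
        cells = np.nonzero(mask)[0]
        pos = {int(c): j for j, c in enumerate(cells)}
        _, S, Q = latent_process_draws(posterior, fold_data, cells=cells)
        s_mean = S.mean(axis=0)
        q_mean = Q.mean(axis=0)

        flabels, fscores = [], []
        for resp in responses:
            cells_r = held[resp]
            labels = (data.y_c[cells_r] if resp == "y_c"
                      else data.y[int(resp[1:]), cells_r])
            scores = np.array([
                s_mean[pos[int(c)]] if resp == "y_c"
                else q_mean[int(resp[1:]), pos[int(c)]]
                for c in cells_r])
            auc = rank_auc(labels, scores)
            rows.append({"fold": f, "response": resp,
                         "n_held_out": int(cells_r.size), "auc": auc})
            pooled[resp][0].extend(labels.tolist())
            pooled[resp][1].extend(scores.tolist())
            flabels.extend(labels.tolist())
            fscores.extend(scores.tolist())
        fold_pooled.append(rank_auc(flabels, fscores))

    all_labels = [v for resp in responses for v in pooled[resp][0]]
    all_scores = [v for resp in responses for v in pooled[resp][1]]
    pooled_auc = rank_auc(all_labels, all_scores)
    _, fpr, tpr = trapezoid_auc(all_labels, all_scores)
    per_taxon = {resp: rank_auc(pooled[resp][0], pooled[resp][1])
                 for resp in responses}
    finite = [a for a in fold_pooled if np.isfinite(a)]
    return CVResult(
        k=k, seed=seed, fold_of_cell=folds,
        table=pd.DataFrame(rows), per_taxon_auc=per_taxon,
        pooled_auc=pooled_auc,
        auc_range=(min(finite), max(finite)) if finite else (np.nan, np.nan),
        roc=(fpr, tpr),
    )


# --------------------------------------------------------------------------
# Map export
# --------------------------------------------------------------------------

def maps_to_csv(maps, lattice: Lattice, path):
    """Flat CSV: cell_id, process, taxon, mean, lo95, hi95."""
    rows = []
    for m in maps:
        for j, cid in enumerate(lattice.cell_ids):
            rows.append({"cell_id": cid, "process": m.process,
                         "taxon": "" if m.taxon is None else m.taxon,
                         "mean": m.mean[j], "lo95": m.lo95[j],
                         "hi95": m.hi95[j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def maps_to_geojson(maps, lattice: Lattice, path=None):
    """GeoJSON FeatureCollection with one probability property per map."""
    obj = lattice.to_geojson()
    for feat_idx, feat in enumerate(obj["features"]):
        for m in maps:
            feat["properties"][m.label] = float(m.mean[feat_idx])
    if path is None:
        return obj
    with open(path, "w") as fh:
        json.dump(obj, fh)
    return None
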