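"""GEBV prediction by GBLUP / GFBLUP and cross-validated accuracy.

Breeding values for unphenotyped (validation) animals are predicted by the
conditional expectation of the multivariate normal model: with reference
phenotypes y_r, covariance V_rr = G_rr s2g + I s2e and fixed mean mu,

    g_hat = s2g * G[:, ref] @ V_rr^{-1} (y_r - mu),

which is exactly the mixed-model-equation solution with missing records.
GFBLUP first collapses the feature and remainder GRMs into
G_total = lambda*Gf + (1-lambda)*Gr with lambda = s2f/(s2f+s2r), then runs
the same computation with total genetic variance s2f + s2r.

Accuracy is the Pearson correlation between predicted GEBV and the corrected
phenotype of validation animals, evaluated by repeated k-fold
cross-validation with variance components re-estimated inside each training
fold (no leakage into the validation animals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import GRM, combine_grm
from .varcomp import VarianceComponents, compute_lambda, reml_single, reml_two

logger = logging.getLogger(__name__)

__all__ = ["MixedModelFit", "CvResult", "gblup_fit", "gfblup_fit",
           "crossvalidate"]


@dataclass
class MixedModelFit:
    mu: float
    gebv: pd.Series = field(repr=False)  # indexed by individual id, all animals
    vc: VarianceComponents | None = None
    scenario: str = ""


@dataclass
class CvResult:
    """Cross-validation accuracies for one trait x scenario."""

    fold_accuracy: list[float]
    fold_size: list[int]
    scenario: str = ""
    trait: str = ""
    seed: int = 0
    n_folds: int = 5
    n_repeats: int = 1

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def se_accuracy(self) -> float:
        a = np.asarray(self.fold_accuracy)
        return float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else np.nan


def _solve_gblup(y_ref, G, ref_idx, s2g, s2e, ridge=1e-6):
    """Core conditional-expectation GBLUP solve on an indexed GRM."""
    n_ref = len(ref_idx)
    V = s2g * G[np.ix_(ref_idx, ref_idx)] + s2e * np.eye(n_ref)
    try:
        c = cho_factor(V)
    except np.linalg.LinAlgError:
        logger.warning("singular V_rr: adding ridge %.1e to the diagonal", ridge)
        c = cho_factor(V + ridge * np.eye(n_ref))
    ones = np.ones(n_ref)
    vinv_y = cho_solve(c, y_ref)
    vinv_1 = cho_solve(c, ones)
    mu = float(ones @ vinv_y) / float(ones @ vinv_1)
    alpha = cho_solve(c, y_ref - mu)
    gebv = s2g * (G[:, ref_idx] @ alpha)
    return mu, gebv


def gblup_fit(
    y_ref,
    G: GRM,
    vc: VarianceComponents,
    validation_ids=(),
    scenario: str = "gblup",
) -> MixedModelFit:
    """GBLUP fit: GEBV for every individual in G, phenotyped or not.

    ``y_ref`` is a Series indexed by reference-individual id (or an array
    covering all non-validation ids of G in order).  Variance components must
    come from the reference animals only.
    """
    ids = list(G.ids)
    val = set(validation_ids)
    ref_ids = [i for i in ids if i not in val]
    if isinstance(y_ref, pd.Series):
        y = y_ref.loc[ref_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(y_ref, dtype=float)
        if len(y) != len(ref_ids):
            raise ValueError("y_ref length does not match reference ids")
    ref_idx = [ids.index(i) for i in ref_ids]
    s2g = vc.genetic_variance
    mu, gebv = _solve_gblup(y, G.matrix, ref_idx, s2g, vc.sigma_e2)
    return MixedModelFit(mu=mu, gebv=pd.Series(gebv, index=ids), vc=vc,
                         scenario=scenario)


def gfblup_fit(
    y_ref,
    Gf: GRM,
    Gr: GRM,
    vc: VarianceComponents,
    validation_ids=(),
    scenario: str = "gfblup",
) -> MixedModelFit:
    """GFBLUP fit via the lambda-combined GRM.

    Requires a two-component fit from ``reml_two``; aborts if the feature
    weight is non-identifiable (Gf == Gr up to numerical noise).
    """
    if not vc.identifiable:
        raise ValueError(
            "feature weight lambda is not identifiable (Gf == Gr); "
            "GFBLUP scenario aborted"
        )
    lam = compute_lambda(vc)
    g_total = combine_grm(Gf, Gr, lam)
    fit = gblup_fit(y_ref, g_total, vc, validation_ids, scenario=scenario)
    return fit


def _fold_assignments(ids, n_folds, rng):
    """Random fold labels with sizes differing by at most one."""
    n = len(ids)
    labels = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(labels)
    return labels


def crossvalidate(
    y_c: pd.Series,
    grms,
    model: str = "gblup",
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    scenario: str = "",
    trait: str = "",
) -> CvResult:
    """Repeated k-fold cross-validated prediction accuracy.

    ``y_c`` is indexed by individual id and must match the GRM ids.  ``grms``
    is a single :class:`GRM` for GBLUP or a ``(Gf, Gr)`` pair for GFBLUP.
    Variance components are re-estimated on the training animals of every
    fold.  A validation fold with zero phenotypic variance is excluded from
    the aggregate and logged.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if model not in ("gblup", "gfblup"):
        raise ValueError(f"unknown model {model!r}")
    if model == "gfblup":
        Gf, Gr = grms
        ids = list(Gf.ids)
        if Gr.ids != ids:
            raise ValueError("Gf and Gr id order differs")
    else:
        G = grms[0] if isinstance(grms, (tuple, list)) else grms
        ids = list(G.ids)
    y = y_c.loc[ids]
    rng = np.random.default_rng(seed)
    accs, sizes = [], []
    for _ in range(n_repeats):
        labels = _fold_assignments(ids, n_folds, rng)
        for fold in range(n_folds):
            val_mask = labels == fold
            val_ids = [i for i, m in zip(ids, val_mask) if m]
            ref_ids = [i for i, m in zip(ids, val_mask) if not m]
            y_ref = y.loc[ref_ids]
            if model == "gblup":
                vc = reml_single(y_ref.to_numpy(), G.submatrix(ref_ids))
                fit = gblup_fit(y_ref, G, vc, validation_ids=val_ids,
                                scenario=scenario)
            else:
                vc = reml_two(
                    y_ref.to_numpy(),
                    Gf.submatrix(ref_ids),
                    Gr.submatrix(ref_ids),
                )
                fit = gfblup_fit(y_ref, Gf, Gr, vc, validation_ids=val_ids,
                                 scenario=scenario)
            y_val = y.loc[val_ids].to_numpy()
            g_val = fit.gebv.loc[val_ids].to_numpy()
            if np.std(y_val) == 0 or np.std(g_val) == 0:
                logger.warning("fold %d: zero variance, accuracy undefined", fold)
                continue
            accs.append(float(np.corrcoef(g_val, y_val)[0, 1]))
            sizes.append(len(val_ids))
    return CvResult(
        fold_accuracy=accs,
        fold_size=sizes,
        scenario=scenario,
        trait=trait,
        seed=seed,
        n_folds=n_folds,
        n_repeats=n_repeats,
    )
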