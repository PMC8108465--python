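"""Genomic prediction (gBLUP) of hybrid phenotypes.

The model is the standard genomic best linear unbiased prediction mixed
model

    y = X beta + Z u + e,  u ~ N(0, K sigma_u^2),  e ~ N(0, I sigma_e^2)

where ``K`` is the centered genomic relationship matrix (cGRM) built
from SNP dosages and the fixed effects ``X`` carry an intercept plus the
maternal and paternal phenotypes of each hybrid, absorbing parental-pool
stratification. Phenotypes enter z-scored within each F1 population and
predictions are back-converted with the training population's
transform.

The API follows the statsmodels convention: :class:`GBLUP` is the model
specification, its :meth:`GBLUP.fit` returns a :class:`GBLUPResults`
holding estimates, uncertainties and a ``summary()`` table, and
prediction for unphenotyped samples hangs off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._reml import SpectralREML, fit_reml
from .design import CrossDesign, cross_id
from .io import GenotypeMatrix, mean_fill

logger = logging.getLogger("hybridforge")


@dataclass
class GRM:
    """Centered genomic relationship matrix over a set of samples."""

    sample_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise ValueError("K shape does not match sample count")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        for s in list(rows) + list(cols):
            if s not in pos:
                raise KeyError(f"sample {s!r} not in GRM")
        ri = [pos[s] for s in rows]
        ci = [pos[s] for s in cols]
        return self.K[np.ix_(ri, ci)]


def compute_cgrm(gm: GenotypeMatrix) -> GRM:
    """K = W W' / p with W the per-variant mean-centered dosage matrix.

    Missing dosages are mean-filled (hence centered to exactly zero) for
    this computation only. A monomorphic-only input yields the zero
    matrix with a warning.
    """
    if gm.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    W = mean_fill(gm.dosages)
    W = W - W.mean(axis=0)
    p = max(gm.n_variants, 1)
    K = W @ W.T / p
    if np.allclose(K, 0.0):
        logger.warning("all variants monomorphic: GRM is the zero matrix")
    return GRM(list(gm.sample_ids), K)


class GBLUP:
    """gBLUP model specification for one trait.

    Parameters
    ----------
    y : array-like
        Phenotypes of the training samples (typically z-scores).
    X : array-like or DataFrame
        Fixed-effect design, usually intercept + maternal BLUP +
        paternal BLUP. A DataFrame's columns become coefficient names.
    grm : GRM
        Relationship matrix covering at least the training samples.
    sample_ids : list of str
        Training sample ids, aligned with ``y`` rows; selects the GRM
        block used for fitting.
    """

    def __init__(self, y, X, grm: GRM, sample_ids: list[str]):
        self.y = np.asarray(y, dtype=float).ravel()
        if isinstance(X, pd.DataFrame):
            self.exog_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != self.y.size:
                X = X.T
            self.exog_names = [f"x{j}" for j in range(X.shape[1])]
        self.X = X
        self.grm = grm
        self.sample_ids = list(sample_ids)
        if len(self.sample_ids) != self.y.size or self.X.shape[0] != self.y.size:
            raise ValueError("y, X and sample_ids lengths disagree")

    def fit(self) -> "GBLUPResults":
        K = self.grm.submatrix(self.sample_ids, self.sample_ids)
        reml = fit_reml(self.y, self.X, K, covariate_names=self.exog_names)
        return GBLUPResults(self, reml)


class GBLUPResults:
    """Fitted gBLUP: variance components, fixed effects and BLUPs."""

    def __init__(self, model: GBLUP, reml: SpectralREML):
        self.model = model
        self._reml = reml
        self.beta = reml.beta
        self.beta_se = reml.beta_se
        self.sigma_u2 = reml.sigma_u2
        self.sigma_e2 = reml.sigma_e2
        self.llf = reml.llf
        self.u_hat = reml.blup_u()

    @property
    def heritability(self) -> float:
        return self._reml.heritability

    def fittedvalues(self) -> np.ndarray:
        return self.model.X @ self.beta + self.u_hat

    def predict(self, grm_full: GRM, X_new, sample_ids: list[str]) -> np.ndarray:
        """Predict phenotypes of unphenotyped samples.

        Candidate random effects come from the cross-relationship block:
        u_c = lam * K_ct (lam K_tt + I)^{-1} (y - X beta); the prediction
        adds the candidate fixed-effect term. Output is on the scale the
        model was fitted on (z-scores if y was z-scored; apply
        ``pheno.inverse_zscore`` with the training population's transform
        for absolute values).
        """
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.model.X.shape[1]:
            raise ValueError("X_new column count differs from training X")
        train = self.model.sample_ids
        K_ct = grm_full.submatrix(list(sample_ids), train)
        r = self._reml.residual_rot()
        # V^{-1} r / sigma_e2-free form: U diag(w) U' r with w = 1/(lam s + 1)
        v_inv_r = self._reml.U @ (self._reml.weights * r)
        u_c = self._reml.lam * (K_ct @ v_inv_r)
        return X_new @ self.beta + u_c

    def summary(self) -> str:
        lines = [
            "gBLUP mixed-model fit (spectral REML)",
            f"  n training samples : {len(self.model.sample_ids)}",
            f"  sigma_u^2          : {self.sigma_u2:.6g}",
            f"  sigma_e^2          : {self.sigma_e2:.6g}",
            f"  h^2 (u fraction)   : {self.heritability:.4f}",
            f"  restricted llf     : {self.llf:.4f}",
            "  fixed effects:",
        ]
        for name, b, se in zip(self.model.exog_names, self.beta, self.beta_se):
            lines.append(f"    {name:<16} {b:>12.6g}  (se {se:.4g})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Evaluation schemes
# ---------------------------------------------------------------------------

@dataclass
class PredictabilityReport:
    """Per-fold Pearson correlations for one evaluation scheme."""

    scheme: str
    trait: str
    folds: pd.DataFrame  # columns: fold, n_train, n_test, r

    @property
    def mean_r(self) -> float:
        return float(self.folds["r"].mean())


def loto_folds(design: CrossDesign, phenotyped: set[str] | None = None):
    """Leave-one-tester-out fold bookkeeping.

    Yields (tester, train cross ids, test cross ids). Only crosses in
    ``phenotyped`` (all crosses if None) participate.
    """
    ids = design.cross_ids()
    testers = [p for _, p in design.crosses]
    keep = [
        (cid, t)
        for cid, t in zip(ids, testers)
        if phenotyped is None or cid in phenotyped
    ]
    for tester in design.paternal_ids:
        test = [cid for cid, t in keep if t == tester]
        train = [cid for cid, t in keep if t != tester]
        if test:
            yield tester, train, test


def _fit_and_score(y_map, X_map, grm, train, test) -> float:
    y_tr = np.array([y_map[s] for s in train])
    X_tr = np.array([X_map[s] for s in train])
    res = GBLUP(y_tr, X_tr, grm, train).fit()
    X_te = np.array([X_map[s] for s in test])
    pred = res.predict(grm, X_te, test)
    obs = np.array([y_map[s] for s in test])
    return float(pearsonr(pred, obs)[0])


def evaluate_leave_one_tester(
    design: CrossDesign,
    grm: GRM,
    y: pd.Series,
    X: pd.DataFrame,
    trait: str = "",
    min_test: int = 3,
) -> PredictabilityReport:
    """One fold per tester: train on all other testers' hybrids, test on
    the held-out tester's hybrids, report per-fold Pearson r.

    ``y`` and ``X`` are indexed by cross id; crosses absent from ``y``
    are treated as unphenotyped. Folds with fewer than ``min_test`` test
    hybrids are skipped with a warning.
    """
    phenotyped = set(y.index)
    y_map = y.to_dict()
    X_map = {s: X.loc[s].to_numpy(dtype=float) for s in X.index}
    rows = []
    for tester, train, test in loto_folds(design, phenotyped):
        if len(test) < min_test:
            logger.warning(
                "tester %s has %d (< %d) test hybrids; fold skipped",
                tester, len(test), min_test,
            )
            continue
        r = _fit_and_score(y_map, X_map, grm, train, test)
        rows.append(
            {"fold": tester, "n_train": len(train), "n_test": len(test), "r": r}
        )
    if not rows:
        raise ValueError("no evaluable folds (need >= 2 phenotyped testers)")
    return PredictabilityReport("leave-one-tester", trait, pd.DataFrame(rows))


def evaluate_tester_swap(
    design: CrossDesign,
    grm: GRM,
    y: pd.Series,
    X: pd.DataFrame,
    tester_a: str,
    tester_b: str,
    maternal_subset: list[str],
    trait: str = "",
) -> PredictabilityReport:
    """Two reciprocal extension folds for a pair of fully-crossed testers.

    The base block is ``maternal_subset`` x all testers; tester A and B
    additionally have hybrids from the remaining maternal lines (their
    extension sets). Fold 1 trains on base + A's extension and predicts
    B's extension; fold 2 swaps the roles.
    """
    sub = set(maternal_subset)
    base = [cross_id(m, p) for m, p in design.crosses if m in sub]
    ext = {
        t: [
            cross_id(m, p)
            for m, p in design.crosses
            if p == t and m not in sub
        ]
        for t in (tester_a, tester_b)
    }
    if not ext[tester_a] or not ext[tester_b]:
        raise ValueError("empty extension set for one of the testers")
    phenotyped = set(y.index)
    y_map = y.to_dict()
    X_map = {s: X.loc[s].to_numpy(dtype=float) for s in X.index}
    rows = []
    for tr_t, te_t in ((tester_a, tester_b), (tester_b, tester_a)):
        train = [s for s in base + ext[tr_t] if s in phenotyped]
        test = [s for s in ext[te_t] if s in phenotyped]
        r = _fit_and_score(y_map, X_map, grm, train, test)
        rows.append(
            {
                "fold": f"train+{tr_t}->predict {te_t}",
                "n_train": len(train),
                "n_test": len(test),
                "r": r,
            }
        )
    return PredictabilityReport("tester-swap", trait, pd.DataFrame(rows))
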