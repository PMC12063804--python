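"""Reference-batch ComBat: empirical-Bayes location/scale harmonization.

The model for feature g of sample j acquired in batch i is

    y_ijg = alpha_g + X_j . beta_g + gamma_ig + delta_ig * eps_ijg

with additive batch effects gamma (normal prior across features) and
multiplicative effects delta (inverse-gamma prior on delta^2).  Reference-
batch mode standardizes with the reference batch's variance and maps every
batch onto the reference, leaving reference samples untouched.  Hyper-
parameters are estimated by the method of moments and posterior point
estimates (gamma*, delta*) are taken in a single non-iterative pass.

The core is the sklearn-style transformer :class:`ReferenceComBat`
operating on long-format feature tables (DataFrames with key columns and
feature columns); :func:`fit`, :func:`transform` and
:func:`harmonize_per_roi` are thin functional wrappers.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

KEY_COLUMNS = ("group", "scan", "roi")
CONSTANT_VAR_EPS = 1e-12


class DesignMatrixError(ValueError):
    """Singular covariate design."""


class UnknownBatchError(KeyError):
    """transform saw a batch label absent at fit time."""


class StratumError(ValueError):
    """An ROI stratum cannot be harmonized (fewer than 2 batches)."""


def _split_columns(table: pd.DataFrame, batch_key: str, covariate_cols):
    covariate_cols = list(covariate_cols or [])
    feature_cols = [
        c for c in table.columns if c not in set(KEY_COLUMNS) | {batch_key} | set(covariate_cols)
    ]
    return covariate_cols, feature_cols


class ReferenceComBat(TransformerMixin, BaseEstimator):
    """Empirical-Bayes batch-effect removal toward a reference batch.

    Parameters
    ----------
    batch_key : str
        Column holding the batch (acquisition group) label.
    reference_batch :
        Batch whose samples are returned unchanged and whose variance
        anchors the standardization.
    covariate_cols : list of str, optional
        Columns of biological covariates to protect (design matrix X).
    eb : bool
        If False, raw per-batch moments are used instead of the EB
        posterior estimates.

    Fitted attributes (per retained feature): ``alpha_``, ``beta_``,
    ``pooled_var_``, ``gamma_star_``, ``delta_star_`` (DataFrames indexed
    by batch), ``hyperparams_``, ``constant_features_``.
    """

    def __init__(
        self,
        batch_key: str = "group",
        reference_batch=7,
        covariate_cols: list[str] | None = None,
        eb: bool = True,
    ):
        self.batch_key = batch_key
        self.reference_batch = reference_batch
        self.covariate_cols = covariate_cols
        self.eb = eb

    # -- estimation -----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "ReferenceComBat":
        table = X
        batches = table[self.batch_key]
        batch_ids = list(pd.unique(batches))
        if self.reference_batch not in batch_ids:
            raise UnknownBatchError(f"reference batch {self.reference_batch!r} not in table")
        if len(batch_ids) < 2:
            # degenerate: single batch equal to reference; identity transform
            logger.info("single-batch table: ComBat fits an identity transform")
        counts = batches.value_counts()
        if (counts < 2).any():
            raise ValueError("every batch needs >= 2 samples")

        covariate_cols, feature_cols = _split_columns(table, self.batch_key, self.covariate_cols)
        Y = table[feature_cols].to_numpy(dtype=float)
        n, G = Y.shape

        # design: intercept + covariates; alpha is taken at the reference
        # batch so that reference samples standardize to mean zero.
        Xd = np.ones((n, 1))
        if covariate_cols:
            Xd = np.hstack([Xd, table[covariate_cols].to_numpy(dtype=float)])
        ref_rows = (batches == self.reference_batch).to_numpy()

        # per-batch means absorbed via batch indicators to avoid biasing
        # beta by unbalanced batch effects
        B = pd.get_dummies(batches).to_numpy(dtype=float)
        design = np.hstack([B, Xd[:, 1:]])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise DesignMatrixError("covariate design is singular (confounded with batch)")
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        n_b = B.shape[1]
        batch_means = coef[:n_b]  # per-batch intercepts
        beta = coef[n_b:]  # covariate coefficients (k, G)
        batch_order = list(pd.get_dummies(batches).columns)
        ref_pos = batch_order.index(self.reference_batch)
        alpha = batch_means[ref_pos]  # reference-batch intercept = grand mean target

        cov_term = Xd[:, 1:] @ beta if covariate_cols else np.zeros((n, G))
        resid_ref = Y[ref_rows] - alpha[None, :] - cov_term[ref_rows]
        pooled_var = resid_ref.var(axis=0, ddof=1)
        constant = pooled_var < CONSTANT_VAR_EPS
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature(s) passed through unadjusted",
                stacklevel=2,
            )
        safe_var = np.where(constant, 1.0, pooled_var)

        Z = (Y - alpha[None, :] - cov_term) / np.sqrt(safe_var[None, :])

        gamma_hat = np.zeros((len(batch_ids), G))
        delta2_hat = np.ones((len(batch_ids), G))
        n_per_batch = np.zeros(len(batch_ids), dtype=int)
        for bi, b in enumerate(batch_ids):
            rows = (batches == b).to_numpy()
            n_per_batch[bi] = rows.sum()
            gamma_hat[bi] = Z[rows].mean(axis=0)
            delta2_hat[bi] = Z[rows].var(axis=0, ddof=1)
        delta2_hat = np.maximum(delta2_hat, CONSTANT_VAR_EPS)

        hyper = {}
        if self.eb:
            gamma_star = np.empty_like(gamma_hat)
            delta2_star = np.empty_like(delta2_hat)
            for bi, b in enumerate(batch_ids):
                g_bar = gamma_hat[bi].mean()
                tau2 = gamma_hat[bi].var(ddof=1) if G > 1 else 1.0
                lam, theta = _invgamma_moments(delta2_hat[bi])
                hyper[str(b)] = {
                    "gamma_bar": float(g_bar),
                    "tau2": float(tau2),
                    "lambda": float(lam),
                    "theta": float(theta),
                }
                m = n_per_batch[bi]
                rows = (batches == b).to_numpy()
                if tau2 < CONSTANT_VAR_EPS:
                    gamma_star[bi] = np.full(G, g_bar)
                else:
                    gamma_star[bi] = (m * tau2 * gamma_hat[bi] + delta2_hat[bi] * g_bar) / (
                        m * tau2 + delta2_hat[bi]
                    )
                sse = ((Z[rows] - gamma_star[bi][None, :]) ** 2).sum(axis=0)
                denom = m / 2.0 + lam - 1.0
                if denom <= 0:  # too few features to moment-match; fall back
                    delta2_star[bi] = delta2_hat[bi]
                else:
                    delta2_star[bi] = (theta + 0.5 * sse) / denom
        else:
            gamma_star = gamma_hat.copy()
            delta2_star = delta2_hat.copy()

        # reference-batch convention: identically 0 / 1
        ref_bi = batch_ids.index(self.reference_batch)
        gamma_star[ref_bi] = 0.0
        delta2_star[ref_bi] = 1.0
        delta2_star = np.maximum(delta2_star, CONSTANT_VAR_EPS)

        self.feature_names_ = feature_cols
        self.covariate_cols_ = covariate_cols
        self.batch_ids_ = batch_ids
        self.alpha_ = pd.Series(alpha, index=feature_cols)
        self.beta_ = pd.DataFrame(beta, index=covariate_cols, columns=feature_cols)
        self.pooled_var_ = pd.Series(pooled_var, index=feature_cols)
        self.gamma_star_ = pd.DataFrame(gamma_star, index=batch_ids, columns=feature_cols)
        self.delta_star_ = pd.DataFrame(np.sqrt(delta2_star), index=batch_ids, columns=feature_cols)
        self.hyperparams_ = hyper
        self.constant_features_ = [f for f, c in zip(feature_cols, constant) if c]
        return self

    # -- application ----------------------------------------------------

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "gamma_star_")
        table = X
        unseen = set(pd.unique(table[self.batch_key])) - set(self.batch_ids_)
        if unseen:
            raise UnknownBatchError(f"unseen batch label(s): {sorted(unseen)}")
        missing = [f for f in self.feature_names_ if f not in table.columns]
        if missing:
            raise KeyError(f"table lacks fitted feature columns: {missing[:5]}...")

        out = table.copy()
        Y = table[self.feature_names_].to_numpy(dtype=float)
        n, G = Y.shape
        cov_term = (
            table[self.covariate_cols_].to_numpy(dtype=float) @ self.beta_.to_numpy()
            if self.covariate_cols_
            else np.zeros((n, G))
        )
        alpha = self.alpha_.to_numpy()
        safe_var = np.where(
            self.pooled_var_.to_numpy() < CONSTANT_VAR_EPS, 1.0, self.pooled_var_.to_numpy()
        )
        Z = (Y - alpha[None, :] - cov_term) / np.sqrt(safe_var[None, :])
        adj = np.empty_like(Z)
        batches = table[self.batch_key]
        for b in pd.unique(batches):
            rows = (batches == b).to_numpy()
            g = self.gamma_star_.loc[b].to_numpy()
            d = self.delta_star_.loc[b].to_numpy()
            adj[rows] = (Z[rows] - g[None, :]) / d[None, :]
        harmonized = adj * np.sqrt(safe_var[None, :]) + alpha[None, :] + cov_term

        # constant features pass through untouched
        const = np.array([f in set(self.constant_features_) for f in self.feature_names_])
        harmonized[:, const] = Y[:, const]
        out[self.feature_names_] = harmonized
        return out

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "gamma_star_")
        payload = {
            "batch_key": self.batch_key,
            "reference_batch": self.reference_batch,
            "eb": self.eb,
            "feature_names": self.feature_names_,
            "covariate_cols": self.covariate_cols_,
            "batch_ids": [int(b) if isinstance(b, (int, np.integer)) else b for b in self.batch_ids_],
            "alpha": self.alpha_.tolist(),
            "beta": self.beta_.to_numpy().tolist(),
            "pooled_var": self.pooled_var_.tolist(),
            "gamma_star": self.gamma_star_.to_numpy().tolist(),
            "delta_star": self.delta_star_.to_numpy().tolist(),
            "hyperparams": self.hyperparams_,
            "constant_features": self.constant_features_,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceComBat":
        d = json.loads(text)
        model = cls(
            batch_key=d["batch_key"],
            reference_batch=d["reference_batch"],
            covariate_cols=d["covariate_cols"] or None,
            eb=d["eb"],
        )
        model.feature_names_ = d["feature_names"]
        model.covariate_cols_ = d["covariate_cols"]
        model.batch_ids_ = d["batch_ids"]
        model.alpha_ = pd.Series(d["alpha"], index=model.feature_names_)
        model.beta_ = pd.DataFrame(
            np.asarray(d["beta"]).reshape(len(model.covariate_cols_), -1)
            if model.covariate_cols_
            else np.zeros((0, len(model.feature_names_))),
            index=model.covariate_cols_,
            columns=model.feature_names_,
        )
        model.pooled_var_ = pd.Series(d["pooled_var"], index=model.feature_names_)
        model.gamma_star_ = pd.DataFrame(
            d["gamma_star"], index=model.batch_ids_, columns=model.feature_names_
        )
        model.delta_star_ = pd.DataFrame(
            d["delta_star"], index=model.batch_ids_, columns=model.feature_names_
        )
        model.hyperparams_ = d["hyperparams"]
        model.constant_features_ = d["constant_features"]
        return model


def _invgamma_moments(delta2_hat: np.ndarray) -> tuple[float, float]:
    """Moment-matched inverse-gamma prior (shape, scale) for batch variances."""
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1) if delta2_hat.size > 1 else 0.0
    if s2 < CONSTANT_VAR_EPS:
        return 2.0 + 1e8, m * (1.0 + 1e8)  # near-degenerate prior pinned at m
    lam = (2.0 * s2 + m**2) / s2
    theta = (m * s2 + m**3) / s2
    return lam, theta


# -- functional wrappers ------------------------------------------------


def fit(
    table: pd.DataFrame,
    batch_key: str = "group",
    covariates: list[str] | None = None,
    reference_batch=7,
    eb: bool = True,
) -> ReferenceComBat:
    return ReferenceComBat(
        batch_key=batch_key, reference_batch=reference_batch, covariate_cols=covariates, eb=eb
    ).fit(table)


def transform(model: ReferenceComBat, table: pd.DataFrame) -> pd.DataFrame:
    return model.transform(table)


def harmonize_per_roi(
    table: pd.DataFrame,
    reference_batch=7,
    batch_key: str = "group",
    covariates: list[str] | None = None,
    eb: bool = True,
) -> pd.DataFrame:
    """Fit+transform independently on each ROI stratum and reassemble.

    Raises :class:`StratumError` naming any ROI stratum with < 2 batches.
    """
    if "roi" not in table.columns:
        raise KeyError("table has no 'roi' column")
    pieces = []
    for roi, sub in table.groupby("roi", sort=False):
        if sub[batch_key].nunique() < 2:
            raise StratumError(f"ROI {roi!r} stratum has fewer than 2 batches")
        model = fit(sub, batch_key, covariates, reference_batch, eb)
        piece = model.transform(sub)
        piece.attrs = {}  # array-valued attrs break pandas concat
        pieces.append(piece)
    out = pd.concat(pieces).loc[table.index]
    out.attrs = dict(table.attrs)
    return out
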