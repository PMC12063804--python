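"""Evaluation of harmonization: reproducibility (Lin's CCC), stability
(paired tests with Bonferroni correction), discriminative power
(cross-validated SVM AUC), achieved power, and image quality
(NMSE/PSNR/SSIM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CONSTANT_VAR_EPS = 1e-12
PSNR_CAP_DB = 100.0

KEY_COLUMNS = ["group", "scan", "roi"]


class ConstantInputError(ValueError):
    """A CCC input vector is constant; the caller should exclude the feature."""


class PairingError(ValueError):
    """Scan indices do not align between a group and the reference group."""


# ---------------------------------------------------------------- CCC


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("ccc needs two equal-length 1D vectors of length >= 2")
    vx, vy = x.var(), y.var()
    if vx < CONSTANT_VAR_EPS or vy < CONSTANT_VAR_EPS:
        raise ConstantInputError("constant input vector")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


# ------------------------------------------------- reproducibility


@dataclass
class ReproducibilityReport:
    records: pd.DataFrame  # columns: feature, roi, group, ccc
    average_ccc: float
    fraction_reproducible: float
    threshold: float
    excluded_features: list[str]
    baseline: "ReproducibilityReport | None" = None

    def summary(self) -> dict:
        out = {
            "average_ccc": self.average_ccc,
            "fraction_reproducible": self.fraction_reproducible,
            "percent_reproducible": 100.0 * self.fraction_reproducible,
            "n_excluded": len(self.excluded_features),
        }
        if self.baseline is not None:
            out["baseline_average_ccc"] = self.baseline.average_ccc
            out["baseline_fraction_reproducible"] = self.baseline.fraction_reproducible
        return out


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def _ccc_records(table: pd.DataFrame, reference_group) -> tuple[pd.DataFrame, list[str]]:
    features = _feature_columns(table)
    groups = [g for g in pd.unique(table["group"]) if g != reference_group]
    if reference_group not in set(table["group"]):
        raise ValueError(f"reference group {reference_group!r} absent")

    # wide per (roi, group): rows = scans, cols = features
    excluded: set[str] = set()
    rows = []
    for roi, sub in table.groupby("roi", sort=False):
        ref = sub[sub["group"] == reference_group].set_index("scan").sort_index()
        for g in groups:
            other = sub[sub["group"] == g].set_index("scan").sort_index()
            if list(other.index) != list(ref.index):
                raise PairingError(
                    f"scan indices of group {g!r} do not match reference in roi {roi!r}"
                )
            for f in features:
                try:
                    c = ccc(ref[f].to_numpy(), other[f].to_numpy())
                except ConstantInputError:
                    excluded.add(f)
                    continue
                rows.append((f, roi, g, c))
    records = pd.DataFrame(rows, columns=["feature", "roi", "group", "ccc"])
    # a feature constant anywhere is excluded everywhere (paper convention)
    records = records[~records["feature"].isin(excluded)]
    return records.reset_index(drop=True), sorted(excluded)


def reproducibility_report(
    table: pd.DataFrame,
    harmonized: pd.DataFrame | None = None,
    reference_group=7,
    threshold: float = 0.95,
) -> ReproducibilityReport:
    """CCC of every (feature, roi, non-reference group) against the
    reference group over scan-paired vectors.

    If ``harmonized`` is given, the report describes the harmonized table
    and carries the non-harmonized report under ``.baseline``.
    """
    target = harmonized if harmonized is not None else table
    records, excluded = _ccc_records(target, reference_group)
    if len(records):
        avg = float(records["ccc"].mean())
        frac = float((records["ccc"] >= threshold).mean())
    else:
        avg, frac = float("nan"), float("nan")
    report = ReproducibilityReport(records, avg, frac, threshold, excluded)
    if harmonized is not None:
        report.baseline = reproducibility_report(
            table, None, reference_group=reference_group, threshold=threshold
        )
    return report


# ------------------------------------------------------- stability


@dataclass
class StabilityReport:
    records: pd.DataFrame  # feature, roi, group, test, p_raw, p_adjusted
    per_roi: pd.DataFrame  # roi, n_stable, n_features, percent_stable
    alpha: float
    n_comparisons: int

    @property
    def average_percent_stable(self) -> float:
        return float(self.per_roi["percent_stable"].mean())


def stability_report(
    table: pd.DataFrame,
    reference_group=7,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> StabilityReport:
    """Paired stability tests of each feature between the reference group
    and every other group, per ROI.

    Paired differences are tested for normality (Shapiro-Wilk at 0.05);
    paired t-test if normal, Wilcoxon signed-rank otherwise.  Raw p-values
    are Bonferroni-adjusted over the group comparisons (``n_comparisons``
    defaults to the number of non-reference groups, 7 in the full study).
    A feature is stable for an ROI when all adjusted p > alpha; all-zero
    differences short-circuit to maximally stable (p = 1).
    """
    features = _feature_columns(table)
    groups = [g for g in pd.unique(table["group"]) if g != reference_group]
    m = n_comparisons if n_comparisons is not None else len(groups)
    rows = []
    for roi, sub in table.groupby("roi", sort=False):
        ref = sub[sub["group"] == reference_group].set_index("scan").sort_index()
        for g in groups:
            other = sub[sub["group"] == g].set_index("scan").sort_index()
            if list(other.index) != list(ref.index):
                raise PairingError(
                    f"scan indices of group {g!r} do not match reference in roi {roi!r}"
                )
            if len(ref) < 3:
                raise ValueError("need >= 3 pairs per comparison")
            for f in features:
                d = other[f].to_numpy() - ref[f].to_numpy()
                if np.allclose(d, 0.0):
                    test, p = "all-zero", 1.0
                elif np.ptp(d) < CONSTANT_VAR_EPS:
                    # constant nonzero difference: an exact systematic shift
                    test, p = "constant-shift", 0.0
                else:
                    sw_p = stats.shapiro(d).pvalue
                    if sw_p > 0.05:
                        test, p = "paired-t", float(stats.ttest_rel(other[f], ref[f]).pvalue)
                    else:
                        nz = d[d != 0.0]
                        if nz.size == 0:
                            test, p = "all-zero", 1.0
                        else:
                            test, p = "wilcoxon", float(stats.wilcoxon(nz).pvalue)
                p_adj = min(1.0, m * p)
                rows.append((f, roi, g, test, p, p_adj))
    records = pd.DataFrame(
        rows, columns=["feature", "roi", "group", "test", "p_raw", "p_adjusted"]
    )
    stable = (
        records.groupby(["roi", "feature"])["p_adjusted"]
        .apply(lambda s: bool((s > alpha).all()))
        .rename("stable")
        .reset_index()
    )
    per_roi = (
        stable.groupby("roi")["stable"]
        .agg(n_stable="sum", n_features="count")
        .reset_index()
    )
    per_roi["percent_stable"] = 100.0 * per_roi["n_stable"] / per_roi["n_features"]
    return StabilityReport(records, per_roi, alpha, m)


# ----------------------------------------------------------- power


def paired_power(effect_size: float, alpha: float = 0.05, n_pairs: int = 30) -> float:
    """Achieved power of a two-sided paired t-test via the noncentral t
    distribution (noncentrality d*sqrt(n), df n-1)."""
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    df = n_pairs - 1
    nc = effect_size * np.sqrt(n_pairs)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


# -------------------------------------------------- discrimination


@dataclass
class ClassificationReport:
    retained_features: list[str]
    dropped_features: list[str]
    per_class_auc: dict
    macro_auc: float
    best_params: dict


def correlation_filter(X: pd.DataFrame, threshold: float = 0.95) -> list[str]:
    """Drop the later column of each pair with |Pearson r| > threshold."""
    corr = X.corr().abs().to_numpy()
    cols = list(X.columns)
    keep: list[int] = []
    for j in range(len(cols)):
        if all(corr[j, k] <= threshold or np.isnan(corr[j, k]) for k in keep):
            keep.append(j)
    return [cols[j] for j in keep]


DEFAULT_GRID = {"svc__C": [0.1, 1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.01, 0.001]}


def discrimination_report(
    table: pd.DataFrame,
    class_key: str = "roi",
    seed: int = 0,
    corr_threshold: float = 0.95,
    n_folds: int = 3,
) -> ClassificationReport:
    """Cross-validated one-vs-rest AUC of an RBF-SVM tissue classifier.

    Highly correlated features are removed (keep-first by column order),
    features standardized, SVM hyperparameters grid-searched under
    stratified k-fold CV, and per-class AUC computed from cross-validated
    decision scores; the macro average is their mean.
    """
    y = table[class_key].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < n_folds).any():
        raise ValueError("every class needs at least n_folds samples")

    features = _feature_columns(table)
    features = [f for f in features if f != class_key]
    Xdf = table[features]
    # constant columns carry no signal and break standardization
    nonconst = [f for f in features if Xdf[f].var() > CONSTANT_VAR_EPS]
    retained = correlation_filter(Xdf[nonconst], corr_threshold)
    dropped = [f for f in features if f not in retained]
    X = Xdf[retained].to_numpy(dtype=float)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", decision_function_shape="ovr"))]
    )
    # hyperparameters tuned on balanced accuracy (margin scores, no
    # probability calibration needed); AUC is the reported metric below
    search = GridSearchCV(pipe, DEFAULT_GRID, cv=cv, scoring="balanced_accuracy", n_jobs=1)
    search.fit(X, y)
    best = search.best_estimator_
    scores = cross_val_predict(best, X, y, cv=cv, method="decision_function")
    if scores.ndim == 1:  # binary: single OvR score for the positive class
        scores = np.column_stack([-scores, scores])
    per_class = {
        (int(c) if isinstance(c, np.integer) else c): float(
            roc_auc_score((y == c).astype(int), scores[:, k])
        )
        for k, c in enumerate(classes)
    }
    macro = float(np.mean(list(per_class.values())))
    return ClassificationReport(retained, dropped, per_class, macro, search.best_params_)


# --------------------------------------------------- image quality


@dataclass
class ImageQualityReport:
    per_image: pd.DataFrame  # index, nmse, psnr, ssim
    nmse: float
    psnr: float
    ssim: float


def nmse(generated: np.ndarray, target: np.ndarray) -> float:
    """||g - t||^2 / ||t||^2."""
    g = np.asarray(generated, float)
    t = np.asarray(target, float)
    denom = (t**2).sum()
    return float(((g - t) ** 2).sum() / denom) if denom > 0 else float((g**2).sum() > 0)


def image_quality(
    generated, target, data_range: float = 1.0, psnr_cap: float = PSNR_CAP_DB
) -> ImageQualityReport:
    """NMSE, PSNR (dB, capped for identical images) and SSIM per image
    and averaged over the set."""
    gen = [np.asarray(g, float) for g in generated]
    tgt = [np.asarray(t, float) for t in target]
    if len(gen) != len(tgt) or any(g.shape != t.shape for g, t in zip(gen, tgt)):
        raise ValueError("generated/target image sets must have matching shapes")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    rows = []
    for g, t in zip(gen, tgt):
        mse = float(((g - t) ** 2).mean())
        psnr = psnr_cap if mse == 0 else min(
            psnr_cap, float(peak_signal_noise_ratio(t, g, data_range=data_range))
        )
        win = min(7, min(t.shape) - (min(t.shape) + 1) % 2)  # odd, <= image size
        ssim = float(structural_similarity(t, g, data_range=data_range, win_size=win))
        rows.append((nmse(g, t), psnr, ssim))
    per_image = pd.DataFrame(rows, columns=["nmse", "psnr", "ssim"])
    return ImageQualityReport(
        per_image,
        float(per_image["nmse"].mean()),
        float(per_image["psnr"].mean()),
        float(per_image["ssim"].mean()),
    )
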