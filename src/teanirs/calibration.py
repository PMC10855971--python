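"""Full MPLS calibration protocol and its validation statistics.

The protocol mirrors standard NIR calibration practice: pretreat the
spectra, eliminate spectral outliers by the global H (GH) Mahalanobis
criterion in principal-component score space (GH >= 3.0), then iterate
{4-group cross-validation to pick the factor count, MPLS fit, removal of
chemical outliers with standardized prediction residual T >= 2.5} for at
most two passes, and report the calibration statistics:

* SEC  = sqrt(SSE / (N - k - 1)), the standard error of calibration;
* SECV = sqrt(mean held-out squared error), from cross-validation;
* RSQ  = 1 - SSE / SST, the multiple correlation coefficient;
* RPD  = SD / SEC, the ratio performance deviation (> 2.5-3 indicates a
  usable quantitative model);
* estimated range = mean +/- 3 SD, clamped at zero below.

External validation reports bias, SEP, bias-corrected SEP(C), RMSE, RSQ and
a two-sided paired t-test between predicted and reference values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

from .dataset import METALS, SampleTable
from .mpls import CrossValidation, MPLSRegression, MPLSResults, cross_validate
from .pretreat import PretreatmentCode, apply_pretreatment, parse_treatment_code

__all__ = [
    "estimated_range",
    "CalibrationStats",
    "ValidationStats",
    "OutlierReport",
    "GHReport",
    "global_h_outliers",
    "t_outliers",
    "calibration_statistics",
    "external_validation",
    "MetalCalibration",
    "MetalCalibrationResults",
]


def estimated_range(mean: float, sd: float) -> tuple[float, float]:
    """Calibration range estimate: mean +/- 3 SD, clamped at zero below."""
    return max(0.0, mean - 3.0 * sd), mean + 3.0 * sd


@dataclass
class GHReport:
    """Global H (Mahalanobis-in-score-space) distances and flags."""

    gh: np.ndarray
    flagged: np.ndarray          # indices with GH >= threshold
    threshold: float
    n_components: int
    explained_variance: float    # cumulative variance fraction of the PCA


def global_h_outliers(
    X: np.ndarray, n_components: int = 10, threshold: float = 3.0
) -> GHReport:
    """Flag spectra far from the population centroid in PCA score space.

    GH_i = (1/k) * sum_j ((t_ij - mean_j) / sd_j)^2 over the k retained
    principal-component scores; a sample with GH >= threshold is a global
    H outlier.
    """
    X = np.asarray(X, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n, p = X.shape
    k = min(n_components, n - 1, p)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    sd = scores.std(axis=0, ddof=1)
    sd[sd <= 1e-14] = 1.0
    z = (scores - scores.mean(axis=0)) / sd
    gh = (z ** 2).mean(axis=1)
    return GHReport(
        gh=gh,
        flagged=np.flatnonzero(gh >= threshold),
        threshold=threshold,
        n_components=k,
        explained_variance=float(pca.explained_variance_ratio_.sum()),
    )


def t_outliers(
    y: np.ndarray, y_hat: np.ndarray, scale: float, threshold: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized prediction residuals T_i = |y_i - yhat_i| / scale.

    Returns (T values, indices with T >= threshold); the boundary value is
    flagged (the criterion is inclusive).
    """
    if scale <= 0:
        raise ValueError("T-criterion scale must be positive")
    t = np.abs(np.asarray(y, float) - np.asarray(y_hat, float)) / scale
    return t, np.flatnonzero(t >= threshold)


@dataclass
class OutlierReport:
    """Samples removed during calibration, by criterion."""

    gh_removed: list = field(default_factory=list)
    t_removed: list = field(default_factory=list)   # one list of ids per pass
    passes: int = 0

    @property
    def all_removed(self) -> list:
        out = list(self.gh_removed)
        for ids in self.t_removed:
            out.extend(ids)
        return out


@dataclass
class CalibrationStats:
    """Table of calibration descriptors for one analyte."""

    analyte: str
    units: str
    n: int
    n_factors: int
    mean: float
    sd: float
    min_est: float
    max_est: float
    sec: float
    secv: float
    rsq: float
    rpd: float
    rpd_infinite: bool = False

    def as_dict(self) -> dict:
        return {
            "analyte": self.analyte, "units": self.units, "N": self.n,
            "n_factors": self.n_factors, "mean": self.mean, "SD": self.sd,
            "min_est": self.min_est, "max_est": self.max_est, "SEC": self.sec,
            "SECV": self.secv, "RSQ": self.rsq, "RPD": self.rpd,
        }


def calibration_statistics(
    y: np.ndarray,
    y_hat: np.ndarray,
    y_cv: np.ndarray,
    n_factors: int,
    analyte: str = "",
    units: str = "",
) -> CalibrationStats:
    """Calibration descriptors from fitted and cross-validated predictions."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    y_cv = np.asarray(y_cv, float)
    n = y.size
    if n <= n_factors + 1:
        raise ValueError("need N > n_factors + 1 calibration samples")
    e = y - y_hat
    sse = float(e @ e)
    sst = float(((y - y.mean()) ** 2).sum())
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    sec = float(np.sqrt(sse / (n - n_factors - 1)))
    secv = float(np.sqrt(np.mean((y - y_cv) ** 2)))
    rsq = 1.0 - sse / sst if sst > 0 else 1.0
    rpd_infinite = sec == 0.0
    if rpd_infinite:
        warnings.warn(f"SEC is zero for {analyte or 'analyte'}; RPD is infinite")
        rpd = float("inf")
    else:
        rpd = sd / sec
    return CalibrationStats(
        analyte=analyte,
        units=units,
        n=n,
        n_factors=n_factors,
        mean=mean,
        sd=sd,
        min_est=estimated_range(mean, sd)[0],
        max_est=estimated_range(mean, sd)[1],
        sec=sec,
        secv=secv,
        rsq=rsq,
        rpd=rpd,
        rpd_infinite=rpd_infinite,
    )


@dataclass
class ValidationStats:
    """External validation descriptors for one analyte."""

    analyte: str
    n: int
    bias: float
    sep: float
    sep_c: float
    rmse: float
    rsq: float
    p_paired_t: float
    degenerate_t: bool = False

    def as_dict(self) -> dict:
        return {
            "analyte": self.analyte, "n": self.n, "bias": self.bias,
            "SEP": self.sep, "SEP(C)": self.sep_c, "RMSE": self.rmse,
            "RSQ": self.rsq, "p_paired_t": self.p_paired_t,
        }


def external_validation(
    y: np.ndarray, y_hat: np.ndarray, analyte: str = ""
) -> ValidationStats:
    """Bias, SEP, SEP(C), RMSE, RSQ and a paired t-test on a held-out set."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    n = y.size
    if n < 3:
        raise ValueError("external validation needs at least 3 samples")
    d = y_hat - y
    bias = float(d.mean())
    sep = float(np.sqrt((d ** 2).sum() / n))
    sep_c = float(np.sqrt(((d - bias) ** 2).sum() / (n - 1)))
    if np.std(y_hat) == 0 or np.std(y) == 0:
        rsq = 0.0
    else:
        rsq = float(np.corrcoef(y, y_hat)[0, 1] ** 2)
    degenerate = float(np.std(d, ddof=1)) == 0.0
    if degenerate:
        p = 1.0 if bias == 0.0 else 0.0
    else:
        p = float(sps.ttest_rel(y_hat, y).pvalue)
    return ValidationStats(
        analyte=analyte,
        n=n,
        bias=bias,
        sep=sep,
        sep_c=sep_c,
        rmse=sep,
        rsq=rsq,
        p_paired_t=p,
        degenerate_t=degenerate,
    )


class MetalCalibration:
    """Full calibration protocol for one analyte on a calibration table.

    ``fit()`` runs pretreatment, GH outlier removal, and up to
    ``max_outlier_passes`` rounds of {cross-validated factor selection,
    MPLS fit, T-criterion removal}, then returns a results object carrying
    the final model, statistics and the outlier log.
    """

    def __init__(
        self,
        table: SampleTable,
        analyte: str,
        pretreatment: str | PretreatmentCode = "Detrend (2,4,4,1)",
        n_groups: int = 4,
        max_factors: int = 16,
        gh_threshold: float = 3.0,
        gh_components: int = 10,
        t_threshold: float = 2.5,
        max_outlier_passes: int = 2,
        seed: int = 0,
    ) -> None:
        if analyte not in METALS:
            raise ValueError(f"unknown analyte {analyte!r}; expected one of {list(METALS)}")
        self.table = table
        self.analyte = analyte
        self.code = (parse_treatment_code(pretreatment)
                     if isinstance(pretreatment, str) else pretreatment)
        self.n_groups = n_groups
        self.max_factors = max_factors
        self.gh_threshold = gh_threshold
        self.gh_components = gh_components
        self.t_threshold = t_threshold
        self.max_outlier_passes = max_outlier_passes
        self.seed = seed

    def fit(self) -> "MetalCalibrationResults":
        pretreated, state = apply_pretreatment(self.table, self.code)
        report = OutlierReport()
        n0 = len(pretreated)

        gh = global_h_outliers(pretreated.spectra, self.gh_components, self.gh_threshold)
        if gh.flagged.size:
            report.gh_removed = list(pretreated.ids[gh.flagged])
            keep = np.setdiff1d(np.arange(len(pretreated)), gh.flagged)
            pretreated = pretreated.take(keep)

        cv: CrossValidation | None = None
        mpls_res: MPLSResults | None = None
        for p in range(self.max_outlier_passes):
            cv = cross_validate(
                pretreated.spectra, pretreated.metal(self.analyte),
                n_groups=self.n_groups, max_factors=self.max_factors,
                seed=self.seed + p,
            )
            y = pretreated.metal(self.analyte)
            mpls_res = MPLSRegression(
                y, pretreated.spectra, pretreated.wavelengths
            ).fit(cv.n_factors)
            sec = np.sqrt(
                float(mpls_res.resid @ mpls_res.resid)
                / max(len(y) - cv.n_factors - 1, 1)
            )
            if sec <= 0:
                report.passes = p + 1
                break
            _, flagged = t_outliers(y, mpls_res.fittedvalues, sec, self.t_threshold)
            report.passes = p + 1
            if flagged.size == 0:
                break
            report.t_removed.append(list(pretreated.ids[flagged]))
            keep = np.setdiff1d(np.arange(len(pretreated)), flagged)
            pretreated = pretreated.take(keep)
            mpls_res = None  # refit below if the loop ends here

        if len(pretreated) < n0 / 2:
            raise RuntimeError(
                f"protocol failure: more than half of the calibration samples "
                f"were removed as outliers for {self.analyte}"
            )
        # Final cross-validation and fit on the cleaned set.
        y = pretreated.metal(self.analyte)
        cv = cross_validate(
            pretreated.spectra, y,
            n_groups=self.n_groups, max_factors=self.max_factors,
            seed=self.seed + self.max_outlier_passes,
        )
        mpls_res = MPLSRegression(
            y, pretreated.spectra, pretreated.wavelengths
        ).fit(cv.n_factors)
        stats = calibration_statistics(
            y, mpls_res.fittedvalues, cv.cv_predictions, cv.n_factors,
            analyte=self.analyte, units=METALS[self.analyte],
        )
        return MetalCalibrationResults(
            model=self,
            mpls=mpls_res,
            stats=stats,
            outliers=report,
            cv=cv,
            pretreat_state=state,
            gh=gh,
            calibration_table=pretreated,
        )


@dataclass
class MetalCalibrationResults:
    """Results of the full protocol: model, statistics, outlier log."""

    model: MetalCalibration
    mpls: MPLSResults
    stats: CalibrationStats
    outliers: OutlierReport
    cv: CrossValidation
    pretreat_state: dict
    gh: GHReport
    calibration_table: SampleTable

    @property
    def analyte(self) -> str:
        return self.model.analyte

    def predict(self, table: SampleTable) -> np.ndarray:
        """Pretreat a raw-spectrum table identically and predict."""
        pretreated, _ = apply_pretreatment(table, self.model.code, self.pretreat_state)
        return self.mpls.predict(pretreated.spectra)

    def validate(self, table: SampleTable) -> ValidationStats:
        """External validation against the table's reference values."""
        y_hat = self.predict(table)
        return external_validation(table.metal(self.analyte), y_hat, self.analyte)

    def to_dict(self) -> dict:
        """JSON-serializable model export (grid, centers, beta, provenance)."""
        return {
            "analyte": self.analyte,
            "units": METALS[self.analyte],
            "pretreatment": str(self.model.code),
            "seed": self.model.seed,
            "n_factors": self.mpls.n_factors,
            "wavelengths": self.mpls.wavelengths.tolist(),
            "x_mean": self.mpls.x_mean.tolist(),
            "y_mean": self.mpls.y_mean,
            "beta0": self.mpls.beta0,
            "beta": self.mpls.beta.tolist(),
            "scales": self.mpls.scales.tolist(),
            "outliers": {
                "gh_removed": [str(s) for s in self.outliers.gh_removed],
                "t_removed": [[str(s) for s in ids] for ids in self.outliers.t_removed],
                "passes": self.outliers.passes,
            },
            "stats": self.stats.as_dict(),
        }

    def summary(self) -> str:
        s = self.stats
        lines = [
            f"MPLS calibration: {self.analyte} ({s.units}), "
            f"pretreatment {self.model.code}",
            f"  N = {s.n} (removed: {len(self.outliers.all_removed)}; "
            f"GH {len(self.outliers.gh_removed)}, "
            f"T {sum(len(i) for i in self.outliers.t_removed)})",
            f"  factors = {s.n_factors}   mean = {s.mean:.4f}   SD = {s.sd:.4f}",
            f"  range est. = [{s.min_est:.3f}, {s.max_est:.3f}]",
            f"  SEC = {s.sec:.4f}   SECV = {s.secv:.4f}   "
            f"RSQ = {s.rsq:.3f}   RPD = {s.rpd:.2f}",
        ]
        return "\n".join(lines)
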