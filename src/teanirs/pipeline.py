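"""End-to-end experiment orchestration and reporting.

Reproduces the shapes of the study's analyses on a (synthetic or loaded)
sample library: per-class metal comparison with ANOVA + Tukey letters,
exploratory PCA of the metal profiles, the five-analyte MPLS
calibration/validation report, and the SIMCA / OPLS-DA / RMS-X
discrimination report for the 6-group and 12-group schemes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .calibration import MetalCalibration
from .dataset import METALS, SampleTable, split_sets
from .discriminate import (
    OPLSDA,
    RMSX,
    SIMCA,
    assign_groups,
    confusion_metrics,
    get_scheme,
)
from .simulate import GeneratorConfig, generate_library

__all__ = [
    "ExperimentConfig",
    "GroupComparisonReport",
    "anova_tukey",
    "group_comparison_table",
    "exploratory_pca",
    "PCAResult",
    "run_quantification_experiment",
    "run_discrimination_experiment",
]


@dataclass
class ExperimentConfig:
    """Validated settings shared by the experiment runners."""

    seed: int = 0
    generator: dict = field(default_factory=dict)
    pretreatment: str = "Detrend (2,4,4,1)"
    analytes: tuple = tuple(METALS)
    cal_fraction: float = 0.8
    folds: int = 4
    scheme: str = "pure_vs_blends"
    methods: tuple = ("rmsx",)
    max_factors: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.cal_fraction < 1:
            raise ValueError("cal_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.analytes) - set(METALS)
        if unknown:
            raise ValueError(f"unknown analytes {sorted(unknown)}")
        get_scheme(self.scheme)
        bad = set(self.methods) - {"simca", "oplsda", "rmsx"}
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("analytes", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analytes"] = list(self.analytes)
        d["methods"] = list(self.methods)
        return d


# ---------------------------------------------------------------------------
# Group comparison (ANOVA + Tukey letters)
# ---------------------------------------------------------------------------


@dataclass
class GroupComparisonReport:
    """Per-group mean +/- SD with ANOVA p and compact letter display."""

    groups: tuple
    table: pd.DataFrame       # index: group; columns: n, mean, sd, letters
    f_statistic: float
    p_value: float
    alpha: float


def _compact_letters(groups, means, nonsig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff they lie in a common retained set; sets
    start from the full group set and are split on each significant pair.
    """
    sets = [set(groups)]
    for a, b in [(g1, g2) for g1 in groups for g2 in groups if g1 < g2]:
        if (a, b) in nonsig_pairs or (b, a) in nonsig_pairs:
            continue
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = [s for s in new_sets
                if s and not any(s < t for t in new_sets)]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: min(means[g] for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_tukey(values, groups, alpha: float = 0.05) -> GroupComparisonReport:
    """One-way ANOVA with Tukey HSD letters at the given alpha."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    names = tuple(dict.fromkeys(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    per = {g: values[groups == g] for g in names}
    if any(v.size < 2 for v in per.values()):
        raise ValueError("need at least two values per group")
    if all(np.std(v) == 0 for v in per.values()):
        raise ValueError("zero within-group variance in every group")
    f_stat, p = sps.f_oneway(*[per[g] for g in names])
    tuk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    uniq = list(tuk.groupsunique)
    nonsig = set()
    for (i, j), rej in zip(combinations(range(len(uniq)), 2), tuk.reject):
        if not rej:
            nonsig.add((uniq[i], uniq[j]))
    means = {g: float(per[g].mean()) for g in names}
    letters = _compact_letters(list(names), means, nonsig)
    table = pd.DataFrame(
        {
            "n": {g: per[g].size for g in names},
            "mean": means,
            "sd": {g: float(per[g].std(ddof=1)) for g in names},
            "letters": letters,
        }
    ).loc[list(names)]
    return GroupComparisonReport(
        groups=names, table=table, f_statistic=float(f_stat),
        p_value=float(p), alpha=alpha,
    )


def group_comparison_table(table: SampleTable, alpha: float = 0.05) -> dict:
    """ANOVA/Tukey comparison of each metal across the pure tea classes."""
    pure = table.take(np.flatnonzero(table.classes != "blend"))
    out = {}
    for m in METALS:
        out[m] = anova_tukey(pure.metal(m), pure.classes, alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# Exploratory PCA of the metal profiles
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray


def exploratory_pca(metals: pd.DataFrame, autoscale: bool = True) -> PCAResult:
    """PCA of a per-sample concentration table.

    With ``autoscale`` each column is centered and scaled to unit SD, so the
    decomposition reflects the correlation structure; variance fractions sum
    to one.
    """
    X = metals.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 variables")
    X = X - X.mean(axis=0)
    if autoscale:
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            raise ValueError(
                f"constant column {metals.columns[bad[0]]!r} cannot be autoscaled"
            )
        X = X / sd
    U, svals, Vt = np.linalg.svd(X, full_matrices=False)
    var = svals ** 2
    frac = var / var.sum()
    k = svals.size
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * svals, columns=pcs, index=metals.index),
        loadings=pd.DataFrame(Vt.T, columns=pcs, index=metals.columns),
        variance_fractions=frac,
    )


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _get_library(config: ExperimentConfig, table: SampleTable | None) -> SampleTable:
    return table if table is not None else generate_library(config.generator_config())


def run_quantification_experiment(
    config: ExperimentConfig, table: SampleTable | None = None
) -> dict:
    """Calibrate and externally validate every analyte; return the report."""
    library = _get_library(config, table)
    cal, val = split_sets(library, config.cal_fraction, seed=config.seed)
    report = {
        "config": config.to_dict(),
        "n_total": len(library),
        "n_calibration": len(cal),
        "n_validation": len(val),
        "calibration": {},
        "validation": {},
        "outliers": {},
    }
    for analyte in config.analytes:
        try:
            res = MetalCalibration(
                cal, analyte,
                pretreatment=config.pretreatment,
                n_groups=config.folds,
                max_factors=config.max_factors,
                seed=config.seed,
            ).fit()
        except RuntimeError as exc:  # protocol failure is reported, not raised
            report["calibration"][analyte] = {"error": str(exc)}
            continue
        report["calibration"][analyte] = res.stats.as_dict()
        report["validation"][analyte] = res.validate(val).as_dict()
        report["outliers"][analyte] = {
            "gh_removed": [str(s) for s in res.outliers.gh_removed],
            "t_removed": [[str(s) for s in ids] for ids in res.outliers.t_removed],
            "passes": res.outliers.passes,
        }
    return _jsonify(report)


def _confusion_dict(rep) -> dict:
    d = rep.as_dict()
    # classes missing from a split produce NaN cells -> reported as None
    return _jsonify(d)


def run_discrimination_experiment(
    config: ExperimentConfig, table: SampleTable | None = None
) -> dict:
    """Fit each requested classifier on the calibration split and report
    calibration and validation confusion metrics for the chosen scheme."""
    library = _get_library(config, table)
    cal, val = split_sets(library, config.cal_fraction, seed=config.seed)
    scheme = get_scheme(config.scheme)
    y_cal = assign_groups(cal, scheme)
    y_val = assign_groups(val, scheme)
    report = {
        "config": config.to_dict(),
        "scheme": scheme.name,
        "classes": list(scheme.classes),
        "methods": {},
    }
    for method in config.methods:
        if method == "rmsx":
            res = RMSX(cal, y_cal, pretreatment=config.pretreatment).fit()
            pred_cal, _ = res.classify(cal)
            pred_val, _ = res.classify(val)
            extra = {}
        elif method == "simca":
            res = SIMCA(cal.spectra, y_cal).fit()
            pred_cal = res.classify(cal.spectra)
            pred_val = res.classify(val.spectra)
            extra = {}
        else:  # oplsda
            res = OPLSDA(cal.spectra, y_cal).fit(seed=config.seed)
            pred_cal = res.classify(cal.spectra)
            pred_val = res.classify(val.spectra)
            extra = {"R2X": res.r2x, "R2": res.r2, "Q2": res.q2}
        report["methods"][method] = {
            "calibration": _confusion_dict(
                confusion_metrics(y_cal, pred_cal, scheme.classes)),
            "validation": _confusion_dict(
                confusion_metrics(y_val, pred_val, scheme.classes)),
            **extra,
        }
    return _jsonify(report)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
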