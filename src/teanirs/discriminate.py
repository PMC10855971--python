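"""Class modelling and discriminant analysis for blend authentication.

Three classifiers over NIR spectra:

* **SIMCA** -- one principal-component model per class (components retained
  while their correlation-scale eigenvalue exceeds 1) with an F-type
  critical limit on the residual distance; samples outside every class
  limit are returned as ``"no class"``.
* **OPLS-DA** -- class-orthogonal spectral variation is removed, then a
  PLS model on the one-hot class encoding; reports R2X, R2 and a
  cross-validated Q2.
* **RMS-X residuals** -- root-mean-square distance of a pretreated spectrum
  to each class's mean pretreated spectrum. The default decision rule
  standardises the RMS by the class's own within-class RMS distribution
  before taking the argmin, so a tight class does not lose its near-miss
  samples to a sprawling neighbour; the plain argmin-RMS rule is available
  with ``rule="raw"``.

Two grouping schemes reproduce the study design: 6 groups (3 pure teas +
3 ">50% blend" classes) and 12 groups (3 teas x purity bins >95%, 95-85%,
85-75%, 75-50%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression

from .dataset import TEA_TYPES, SampleTable
from .pretreat import PretreatmentCode, apply_pretreatment, parse_treatment_code

__all__ = [
    "GroupingScheme",
    "PURE_VS_BLENDS",
    "BLEND_PERCENTAGE",
    "assign_groups",
    "SIMCA",
    "SIMCAResults",
    "OPLSDA",
    "OPLSDAResults",
    "RMSX",
    "RMSXResults",
    "ConfusionReport",
    "confusion_metrics",
]

NO_CLASS = "no class"


@dataclass(frozen=True)
class GroupingScheme:
    """Named mapping from blend composition to an ordered set of classes."""

    name: str
    classes: tuple


PURE_VS_BLENDS = GroupingScheme(
    "pure_vs_blends",
    ("black pure", "red pure", "green pure",
     "black blends", "red blends", "green blends"),
)

_PCT_BINS = (">95%", "95-85%", "85-75%", "75-50%")
BLEND_PERCENTAGE = GroupingScheme(
    "blend_percentage",
    tuple(f"{b} {t}" for t in ("black", "red", "green") for b in _PCT_BINS),
)

_SCHEMES = {s.name: s for s in (PURE_VS_BLENDS, BLEND_PERCENTAGE)}


def get_scheme(name: str) -> GroupingScheme:
    if isinstance(name, GroupingScheme):
        return name
    try:
        return _SCHEMES[name.replace("-", "_")]
    except KeyError:
        raise ValueError(f"unknown grouping scheme {name!r}") from None


def assign_groups(table: SampleTable, scheme: GroupingScheme | str) -> np.ndarray:
    """Deterministic class label per sample under the given scheme.

    Purity bins work on the dominant fraction as an integer percentage:
    >95 (pure samples included), 95-85 (boundary 85 and 95 inclusive),
    85-75 and 75-50; a dominant fraction below 50% is outside the design.
    """
    scheme = get_scheme(scheme)
    types, fr = table.dominant()
    pct = np.rint(fr * 100).astype(int)
    if np.any(pct < 50):
        raise ValueError("dominant fraction below 50% is outside the blend design")
    labels = np.empty(len(table), dtype=object)
    for i, (t, p) in enumerate(zip(types, pct)):
        if scheme.name == "pure_vs_blends":
            labels[i] = f"{t} pure" if p == 100 else f"{t} blends"
        else:
            if p > 95:
                b = ">95%"
            elif p >= 85:
                b = "95-85%"
            elif p >= 75:
                b = "85-75%"
            else:
                b = "75-50%"
            labels[i] = f"{b} {t}"
    return labels


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------


class SIMCA:
    """Soft independent modelling of class analogy on whole spectra.

    The data are normalized (per-spectrum SNV), autoscaled and mean-centered
    using training statistics; each class then gets its own PCA model whose
    component count is the number of eigenvalues > 1 (at least one), and a
    residual critical limit from an F bound at ``alpha``.
    """

    def __init__(self, X: np.ndarray, labels, alpha: float = 0.05,
                 normalize: bool = True) -> None:
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(labels, dtype=object)
        if self.X.shape[0] != self.labels.size:
            raise ValueError("X and labels disagree on the sample count")
        self.alpha = alpha
        self.normalize = normalize
        self.classes = tuple(dict.fromkeys(self.labels))  # first-seen order
        counts = pd.Series(self.labels).value_counts()
        small = [c for c in self.classes if counts[c] < 3]
        if small:
            raise ValueError(f"SIMCA needs >= 3 samples per class; too few in {small}")

    def _snv(self, X: np.ndarray) -> np.ndarray:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd <= 1e-14] = 1.0
        return (X - X.mean(axis=1, keepdims=True)) / sd

    def fit(self) -> "SIMCAResults":
        X = self._snv(self.X) if self.normalize else self.X
        col_mean = X.mean(axis=0)
        col_sd = X.std(axis=0, ddof=1)
        col_sd = np.where(col_sd <= 1e-14, 1.0, col_sd)
        Z = (X - col_mean) / col_sd
        p = Z.shape[1]
        class_models = {}
        for c in self.classes:
            Zc = Z[self.labels == c]
            n_c = Zc.shape[0]
            center = Zc.mean(axis=0)
            A = Zc - center
            _, svals, Vt = np.linalg.svd(A, full_matrices=False)
            eig = svals ** 2 / (n_c - 1)
            k = int(np.sum(eig > 1.0))
            k = max(1, min(k, n_c - 2)) if n_c > 2 else 1
            V = Vt[:k].T
            resid = A - (A @ V) @ V.T
            df_resid = max(n_c - k - 1, 1) * (p - k)
            s0_sq = float((resid ** 2).sum()) / df_resid
            s0_sq = max(s0_sq, 1e-30)
            f_crit = sps.f.ppf(1.0 - self.alpha, p - k, df_resid)
            class_models[c] = {
                "center": center,
                "components": V,
                "n_components": k,
                "eigenvalues": eig,
                "s0_sq": s0_sq,
                "crit_sq": s0_sq * f_crit,
            }
        return SIMCAResults(
            model=self, col_mean=col_mean, col_sd=col_sd, class_models=class_models
        )


@dataclass
class SIMCAResults:
    model: SIMCA
    col_mean: np.ndarray
    col_sd: np.ndarray
    class_models: dict

    @property
    def classes(self) -> tuple:
        return self.model.classes

    def distances(self, X: np.ndarray) -> pd.DataFrame:
        """Standardized residual distance of each sample to each class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.col_mean.size:
            raise ValueError("spectrum length does not match the fitted grid")
        if self.model.normalize:
            X = self.model._snv(X)
        Z = (X - self.col_mean) / self.col_sd
        p = Z.shape[1]
        out = {}
        for c, m in self.class_models.items():
            A = Z - m["center"]
            resid = A - (A @ m["components"]) @ m["components"].T
            s_sq = (resid ** 2).sum(axis=1) / (p - m["n_components"])
            out[c] = np.sqrt(s_sq / m["s0_sq"])
        return pd.DataFrame(out)

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Minimal-distance class, or ``"no class"`` outside every limit."""
        d = self.distances(X)
        labels = d.idxmin(axis=1).to_numpy(dtype=object)
        for i in range(len(d)):
            inside = False
            for c, m in self.class_models.items():
                if d.iloc[i][c] ** 2 * m["s0_sq"] <= m["crit_sq"]:
                    inside = True
                    break
            if not inside:
                labels[i] = NO_CLASS
        return labels

    def summary(self) -> str:
        lines = ["SIMCA class models (eigenvalue > 1 rule)"]
        for c, m in self.class_models.items():
            lines.append(
                f"  {c}: {m['n_components']} PCs, "
                f"residual s0 = {np.sqrt(m['s0_sq']):.4g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


class OPLSDA:
    """Orthogonal projections to latent structures discriminant analysis.

    Variation in X uncorrelated with the one-hot class encoding is removed
    by ``n_orthogonal`` orthogonal components, then a PLS model with
    ``n_predictive`` components is fitted to the filtered data; samples are
    assigned to the class with the largest predicted score.
    """

    def __init__(self, X: np.ndarray, labels, n_predictive: int = 2,
                 n_orthogonal: int = 2) -> None:
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(labels, dtype=object)
        self.classes = tuple(dict.fromkeys(self.labels))
        if len(self.classes) < 2:
            raise ValueError("OPLS-DA needs at least two classes")
        n, p = self.X.shape
        if n_predictive < 1 or n_predictive + n_orthogonal > min(n - 1, p):
            raise ValueError("component counts exceed the rank of the data")
        self.n_predictive = n_predictive
        self.n_orthogonal = n_orthogonal

    def _one_hot(self, labels) -> np.ndarray:
        Y = np.zeros((len(labels), len(self.classes)))
        index = {c: j for j, c in enumerate(self.classes)}
        for i, lab in enumerate(labels):
            Y[i, index[lab]] = 1.0
        return Y

    @staticmethod
    def _orthogonal_filter(Xc: np.ndarray, Yc: np.ndarray, n_orthogonal: int):
        """Strip Y-orthogonal components; returns (filtered X, w_o, p_o lists)."""
        W_o, P_o = [], []
        for _ in range(n_orthogonal):
            U, _, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
            w = U[:, 0]
            t = Xc @ w
            p_load = Xc.T @ t / float(t @ t)
            w_o = p_load - U @ (U.T @ p_load)
            norm = np.linalg.norm(w_o)
            if norm <= 1e-12:
                break
            w_o /= norm
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / float(t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
        return Xc, W_o, P_o

    def fit(self, compute_q2: bool = True, q2_folds: int = 7,
            seed: int = 0) -> "OPLSDAResults":
        Y = self._one_hot(self.labels)
        x_mean = self.X.mean(axis=0)
        Xc = self.X - x_mean
        ssx = float((Xc ** 2).sum())
        Yc = Y - Y.mean(axis=0)
        ssy = float((Yc ** 2).sum())
        Xf, W_o, P_o = self._orthogonal_filter(Xc.copy(), Yc, self.n_orthogonal)
        pls = PLSRegression(n_components=self.n_predictive, scale=False)
        pls.fit(Xf, Y)
        Y_hat = pls.predict(Xf)
        r2 = 1.0 - float(((Y - Y_hat) ** 2).sum()) / ssy
        X_resid = Xf - pls.x_scores_ @ pls.x_loadings_.T
        r2x = 1.0 - float((X_resid ** 2).sum()) / ssx if ssx > 0 else 0.0
        q2 = np.nan
        if compute_q2:
            q2 = self._q2(Y, ssy, q2_folds, seed)
        return OPLSDAResults(
            model=self, x_mean=x_mean, w_ortho=W_o, p_ortho=P_o, pls=pls,
            r2x=r2x, r2=r2, q2=q2,
        )

    def _q2(self, Y: np.ndarray, ssy: float, folds: int, seed: int) -> float:
        n = self.X.shape[0]
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        press = 0.0
        for f in np.array_split(order, min(folds, n)):
            train = np.setdiff1d(np.arange(n), f)
            x_mean = self.X[train].mean(axis=0)
            Xc = self.X[train] - x_mean
            Yc = Y[train] - Y[train].mean(axis=0)
            n_ortho = min(self.n_orthogonal, max(len(train) - 1 - self.n_predictive, 0))
            Xf, W_o, P_o = self._orthogonal_filter(Xc.copy(), Yc, n_ortho)
            pls = PLSRegression(n_components=self.n_predictive, scale=False)
            pls.fit(Xf, Y[train])
            Z = self.X[f] - x_mean
            for w_o, p_o in zip(W_o, P_o):
                t_o = Z @ w_o
                Z = Z - np.outer(t_o, p_o)
            press += float(((Y[f] - pls.predict(Z)) ** 2).sum())
        return 1.0 - press / ssy


@dataclass
class OPLSDAResults:
    model: OPLSDA
    x_mean: np.ndarray
    w_ortho: list
    p_ortho: list
    pls: PLSRegression
    r2x: float
    r2: float
    q2: float

    @property
    def classes(self) -> tuple:
        return self.model.classes

    def orthogonal_scores(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model.X if X is None else np.atleast_2d(np.asarray(X, float))
        Z = X - self.x_mean
        scores = []
        for w_o, p_o in zip(self.w_ortho, self.p_ortho):
            t_o = Z @ w_o
            scores.append(t_o)
            Z = Z - np.outer(t_o, p_o)
        return np.column_stack(scores) if scores else np.empty((X.shape[0], 0))

    def _filter(self, X: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(X, float)) - self.x_mean
        for w_o, p_o in zip(self.w_ortho, self.p_ortho):
            t_o = Z @ w_o
            Z = Z - np.outer(t_o, p_o)
        return Z

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(self._filter(X))

    def classify(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        idx = np.argmax(scores, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]

    def scores(self, X: np.ndarray | None = None) -> np.ndarray:
        """Predictive score coordinates (for score plots)."""
        X = self.model.X if X is None else X
        return self._filter(X) @ self.pls.x_rotations_

    def summary(self) -> str:
        return (
            f"OPLS-DA: {self.model.n_predictive} predictive + "
            f"{len(self.w_ortho)} orthogonal components\n"
            f"  R2X = {self.r2x:.3f}  R2 = {self.r2:.3f}  Q2 = {self.q2:.3f}"
        )


# ---------------------------------------------------------------------------
# RMS-X residuals
# ---------------------------------------------------------------------------


class RMSX:
    """RMS-X residual class models on pretreated spectra.

    For a spectrum x and class mean m_c on the p effective wavelengths,
    RMS_c(x) = sqrt( (1/p) * sum_j (x_j - m_cj)^2 ). The fitted model stores
    each class's mean spectrum and the mean/SD of the within-class RMS
    distribution, plus a decision-limit multiplier.

    Accepts either a :class:`SampleTable` (the pretreatment code is applied
    internally) or an already-pretreated matrix.
    """

    def __init__(self, data, labels, pretreatment: str | PretreatmentCode | None = None,
                 limit_multiplier: float = 2.5) -> None:
        if isinstance(data, SampleTable):
            code = pretreatment if pretreatment is not None else "none (0,0,1,1)"
            pretreated, state = apply_pretreatment(data, code)
            self.X = pretreated.spectra
            self.wavelengths = pretreated.wavelengths
            self.pretreat_state = state
            self.code = (parse_treatment_code(code) if isinstance(code, str) else code)
        else:
            if pretreatment is not None:
                raise ValueError("pretreatment codes require a SampleTable input")
            self.X = np.asarray(data, dtype=float)
            self.wavelengths = np.arange(self.X.shape[1], dtype=float)
            self.pretreat_state = {}
            self.code = None
        self.labels = np.asarray(labels, dtype=object)
        if self.X.shape[0] != self.labels.size:
            raise ValueError("data and labels disagree on the sample count")
        counts = pd.Series(self.labels).value_counts()
        small = [c for c in dict.fromkeys(self.labels) if counts[c] < 2]
        if small:
            raise ValueError(f"RMS-X needs >= 2 samples per class; too few in {small}")
        self.limit_multiplier = limit_multiplier

    def fit(self) -> "RMSXResults":
        classes = tuple(dict.fromkeys(self.labels))
        means, rms_mean, rms_sd, n_per = {}, {}, {}, {}
        for c in classes:
            Xc = self.X[self.labels == c]
            n_c = Xc.shape[0]
            m = Xc.mean(axis=0)
            means[c] = m
            r = np.sqrt(((Xc - m) ** 2).mean(axis=1))
            # Training RMS to a mean fitted on the same samples underestimates
            # the RMS of an unseen class member; rescale to the new-sample
            # distribution (E[new RMS^2] / E[train RMS^2] = (n+1)/(n-1)).
            adj = np.sqrt((n_c + 1.0) / (n_c - 1.0))
            rms_mean[c] = float(r.mean() * adj)
            rms_sd[c] = float(max(r.std(ddof=1) * adj, 1e-12))
            n_per[c] = n_c
        return RMSXResults(
            model=self, classes=classes, class_means=means,
            rms_mean=rms_mean, rms_sd=rms_sd, class_sizes=n_per,
        )


@dataclass
class RMSXResults:
    model: RMSX
    classes: tuple
    class_means: dict
    rms_mean: dict
    rms_sd: dict
    class_sizes: dict = field(default_factory=dict)

    def _pretreat(self, data) -> np.ndarray:
        if isinstance(data, SampleTable):
            if self.model.code is None:
                raise ValueError("model was fitted on a raw matrix; pass a matrix")
            pretreated, _ = apply_pretreatment(
                data, self.model.code, self.model.pretreat_state
            )
            return pretreated.spectra
        return np.atleast_2d(np.asarray(data, dtype=float))

    def rms_table(self, data) -> pd.DataFrame:
        """RMS distance of each sample to each class mean."""
        X = self._pretreat(data)
        if X.shape[1] != next(iter(self.class_means.values())).size:
            raise ValueError("spectrum length does not match the fitted grid")
        return pd.DataFrame(
            {c: np.sqrt(((X - m) ** 2).mean(axis=1))
             for c, m in self.class_means.items()}
        )

    def classify(self, data, rule: str = "standardized"):
        """Assign each sample to a class; returns (labels, RMS table).

        ``rule="standardized"`` (default) first builds the candidate set of
        classes whose decision limit accepts the sample -- RMS within
        mean + ``limit_multiplier`` * SD of the class's within-class RMS
        distribution -- and assigns the nearest (smallest raw RMS) candidate;
        a sample no class accepts goes to the least atypical class (smallest
        standardized exceedance). This keeps a tight class from losing its
        members to a sprawling neighbour without rewarding "closer than a
        typical member" artefacts. ``rule="raw"`` is the plain argmin of RMS.
        Exact ties go to the first class in model order, with a warning.
        """
        rms = self.rms_table(data)
        r = rms.to_numpy()
        cl = np.asarray(self.classes, dtype=object)
        if rule == "raw":
            idx = np.argmin(r, axis=1)
            n_min = (r == r[np.arange(len(r)), idx][:, None]).sum(axis=1)
        elif rule == "standardized":
            mu = np.array([self.rms_mean[c] for c in self.classes])
            sd = np.array([self.rms_sd[c] for c in self.classes])
            z = (r - mu) / sd
            k = self.model.limit_multiplier
            accepted = z <= k
            masked = np.where(accepted, r, np.inf)
            idx = np.where(accepted.any(axis=1),
                           np.argmin(masked, axis=1), np.argmin(z, axis=1))
            chosen = np.where(accepted.any(axis=1),
                              masked[np.arange(len(r)), idx],
                              z[np.arange(len(r)), idx])
            field_ = np.where(accepted.any(axis=1)[:, None], masked, z)
            n_min = (field_ == chosen[:, None]).sum(axis=1)
        else:
            raise ValueError(f"unknown decision rule {rule!r}")
        if np.any(n_min > 1):
            warnings.warn(
                f"{int((n_min > 1).sum())} sample(s) equidistant between classes; "
                "assigned to the first class in model order"
            )
        return cl[idx], rms

    def outside_limit(self, data) -> np.ndarray:
        """True where the best-class RMS exceeds mean + multiplier * SD."""
        labels, rms = self.classify(data)
        lim = {c: self.rms_mean[c] + self.model.limit_multiplier * self.rms_sd[c]
               for c in self.classes}
        best = rms.to_numpy()[np.arange(len(rms)),
                              [list(self.classes).index(l) for l in labels]]
        return best > np.array([lim[l] for l in labels])

    def summary(self) -> str:
        lines = [f"RMS-X residual class models ({self.model.code or 'raw input'})"]
        for c in self.classes:
            lines.append(
                f"  {c}: within-RMS {self.rms_mean[c]:.4g} +/- {self.rms_sd[c]:.4g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionReport:
    """Per-class sensitivity/specificity and % correctly classified."""

    classes: tuple
    matrix: pd.DataFrame          # rows: true class, columns: predicted
    per_class: pd.DataFrame       # pct_correct, sensitivity, specificity, n
    overall_accuracy: float

    def as_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "overall_accuracy": self.overall_accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def confusion_metrics(true_labels, predicted_labels, classes) -> ConfusionReport:
    """Confusion counts, sensitivity, specificity and % correct per class.

    True labels must belong to ``classes``; predictions may additionally be
    ``"no class"`` (counted as a misclassification of the true class that is
    assigned to no other class).
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.size != predicted_labels.size:
        raise ValueError("label vectors are not aligned")
    classes = tuple(classes)
    cset = set(classes)
    bad = [l for l in true_labels if l not in cset]
    if bad:
        raise ValueError(f"true label {bad[0]!r} outside the class set")
    bad = [l for l in predicted_labels if l not in cset and l != NO_CLASS]
    if bad:
        raise ValueError(f"predicted label {bad[0]!r} outside the class set")
    cols = classes + ((NO_CLASS,) if NO_CLASS in set(predicted_labels) else ())
    mat = pd.DataFrame(0, index=classes, columns=cols, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        mat.loc[t, p] += 1
    n = true_labels.size
    rows = {}
    for c in classes:
        tp = int(mat.loc[c, c])
        fn = int(mat.loc[c].sum()) - tp
        fp = int(mat[c].sum()) - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        rows[c] = {
            "n": tp + fn,
            "pct_correct": 100.0 * sens if not np.isnan(sens) else np.nan,
            "sensitivity": sens,
            "specificity": spec,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    overall = float((true_labels == predicted_labels).sum()) / n
    return ConfusionReport(
        classes=classes, matrix=mat, per_class=per_class,
        overall_accuracy=overall,
    )
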