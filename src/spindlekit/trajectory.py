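"""Developmental trajectory modeling: LOOCV model selection, bootstrap
localization of interior extrema (the transient quiescent nadir), the
combinatorial maturation metric, and the coarse maturity classifier.

Each animal (or human subject) contributes one summary value per feature at
its age. Candidate models are polynomials of degree 1..d_max in age; the
degree minimizing leave-one-out cross-validated MSE wins. When the selected
model admits interior extrema, the nadir age is localized by resampling
animals with replacement within each age group (jittering ages uniformly over
a +-0.25 age-unit window, total 0.5 as stated for days and weeks), refitting,
and recording the age of the first interior extremum; the null distribution
repeats this with resampling across all ages, which destroys the age
structure while preserving the marginal value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ModelFit",
    "NadirResult",
    "fit_trajectory",
    "bootstrap_nadir",
    "combinatorial_metric",
    "maturity_tree",
    "first_interior_extremum",
]

D_MAX = 5
JITTER_WINDOW = 0.5  # total window, age units (days or weeks)


@dataclass
class ModelFit:
    degree: int
    coefficients: np.ndarray  # numpy polyval order (highest power first)
    loocv_mse: float
    loocv_se: float = 0.0  # standard error of the LOOCV MSE
    residual_by_age: pd.Series | None = None

    @property
    def family(self) -> str:
        return "linear" if self.degree == 1 else "polynomial"

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, ages)


@dataclass
class NadirResult:
    ages: np.ndarray  # distribution support (the observed age grid)
    within_mass: np.ndarray  # P(first extremum at age), within-age resampling
    within_none: float  # P(no interior extremum)
    null_mass: np.ndarray  # same under across-age resampling
    null_none: float
    mode_age: float
    exceedance: float  # within mass at mode / null mass at mode
    n_boot: int


def _loocv_errors(ages: np.ndarray, values: np.ndarray, degree: int) -> np.ndarray:
    n = ages.size
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        c = np.polyfit(ages[m], values[m], degree)
        errs[i] = (values[i] - np.polyval(c, ages[i])) ** 2
    return errs


def _loocv_mse(ages: np.ndarray, values: np.ndarray, degree: int) -> float:
    return float(_loocv_errors(ages, values, degree).mean())


def fit_trajectory(
    data: pd.DataFrame,
    d_max: int = D_MAX,
    age_col: str = "age",
    value_col: str = "value",
    rule: str = "1se",
) -> tuple[ModelFit, list[ModelFit]]:
    """Fit polynomial trajectories of degree 1..d_max, select by LOOCV MSE.

    Each row is one animal's summary value; LOOCV leaves out one animal.
    ``rule='1se'`` (default) selects the lowest degree whose LOOCV MSE lies
    within one standard error of the minimum — the usual guard against the
    selection inconsistency of cross-validation, which otherwise prefers an
    overfit degree on a substantial fraction of truly low-order cohorts.
    ``rule='min'`` takes the strict minimum. Returns (best fit, all
    candidates). The residual diagnostic records the mean residual per age
    for the selected model (a linear fit whose residuals deviate
    systematically from zero at particular ages is the signature of an
    unmodeled nonlinearity).
    """
    ages = data[age_col].to_numpy(dtype=float)
    values = data[value_col].to_numpy(dtype=float)
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    if ages.size <= d_max + 1:
        raise ValueError(f"need more than d_max + 1 = {d_max + 1} animals")
    candidates = []
    for deg in range(1, d_max + 1):
        errs = _loocv_errors(ages, values, deg)
        candidates.append(
            ModelFit(
                degree=deg,
                coefficients=np.polyfit(ages, values, deg),
                loocv_mse=float(errs.mean()),
                loocv_se=float(errs.std(ddof=1) / np.sqrt(errs.size)),
            )
        )
    i_min = int(np.argmin([m.loocv_mse for m in candidates]))
    min_mse = candidates[i_min].loocv_mse
    if rule == "1se":
        margin = candidates[i_min].loocv_se
    elif rule == "min":
        margin = 0.0
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    # tiny epsilon breaks exact ties (noiseless data fits at every degree)
    best = next(m for m in candidates if m.loocv_mse <= min_mse + margin + 1e-12)
    resid = values - best.predict(ages)
    best.residual_by_age = pd.Series(resid).groupby(ages).mean()
    return best, candidates


def first_interior_extremum(coeffs: np.ndarray, lo: float, hi: float) -> float | None:
    """Smallest age in (lo, hi) where the fitted derivative changes sign."""
    der = np.polyder(coeffs)
    if der.size < 2:
        return None
    roots = np.roots(der)
    real = np.sort(np.array([r.real for r in roots if abs(r.imag) < 1e-9 and lo < r.real < hi]))
    for r in real:
        eps = min(r - lo, hi - r) * 1e-3
        if np.sign(np.polyval(der, r - eps)) != np.sign(np.polyval(der, r + eps)):
            return float(r)
    return None


def bootstrap_nadir(
    data: pd.DataFrame,
    degree: int,
    n_boot: int = 10_000,
    jitter_window: float = JITTER_WINDOW,
    seed: int = 0,
    age_col: str = "age",
    value_col: str = "value",
) -> NadirResult:
    """Bootstrap the location of the trajectory's first interior extremum.

    Within-age resampling draws animals with replacement within each age
    group; the null resamples across all ages. Each resample jitters ages
    uniformly over +-jitter_window/2, refits the chosen degree, and records
    the age of the first interior extremum (binned to the nearest observed
    age) or "none". Reproducible bit-for-bit given the seed.
    """
    if degree < 2:
        raise ValueError("degree-1 model admits no interior extremum; skip the bootstrap")
    ages = data[age_col].to_numpy(dtype=float)
    values = data[value_col].to_numpy(dtype=float)
    grid = np.unique(ages)
    lo, hi = grid.min(), grid.max()
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(ages == a) for a in grid]

    def run(within: bool) -> tuple[np.ndarray, float]:
        hits = np.zeros(grid.size)
        none = 0
        n = ages.size
        for _ in range(n_boot):
            if within:
                idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
                v = values[idx]
                a = ages[idx]
            else:
                # across-age resampling: values drawn with replacement from the
                # pooled cohort regardless of age, destroying the age structure
                # while preserving the marginal value distribution
                v = values[rng.choice(n, size=n, replace=True)]
                a = ages
            a = a + rng.uniform(-jitter_window / 2, jitter_window / 2, n)
            c = np.polyfit(a, v, degree)
            ext = first_interior_extremum(c, lo, hi)
            if ext is None:
                none += 1
            else:
                hits[np.argmin(np.abs(grid - ext))] += 1
        return hits / n_boot, none / n_boot

    within_mass, within_none = run(within=True)
    null_mass, null_none = run(within=False)
    mode_i = int(np.argmax(within_mass))
    mode_age = float(grid[mode_i])
    null_at_mode = null_mass[mode_i]
    exceedance = float(within_mass[mode_i] / null_at_mode) if null_at_mode > 0 else np.inf
    return NadirResult(
        ages=grid,
        within_mass=within_mass,
        within_none=within_none,
        null_mass=null_mass,
        null_none=null_none,
        mode_age=mode_age,
        exceedance=exceedance,
        n_boot=n_boot,
    )


def combinatorial_metric(
    features: pd.DataFrame,
    rule: str = "zmean",
    asym_col: str = "asymmetry",
    extent_col: str = "extent",
    power_col: str = "power",
) -> pd.DataFrame:
    """Combine asymmetry (A), spatial extent (S) and power (P) per animal.

    The default rule is the mean of (z(S), -z(A), -z(P)) with within-cohort
    z-scoring, so maturation (extent up, asymmetry and power down) increases
    the metric; it is invariant to per-feature affine rescaling.
    Alternatives: 'pc1' (first principal component, oriented so extent loads
    positively). The rule id is recorded in the output.
    """
    for col in (asym_col, extent_col, power_col):
        if col not in features.columns or features[col].isna().any():
            raise ValueError(f"missing feature column or NaN values: {col}")

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    a = z(features[asym_col].to_numpy(dtype=float))
    s = z(features[extent_col].to_numpy(dtype=float))
    p = z(features[power_col].to_numpy(dtype=float))
    if rule == "zmean":
        metric = (s - a - p) / 3
    elif rule == "pc1":
        X = np.column_stack([s, -a, -p])
        _, _, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        pc = vt[0]
        if pc[0] < 0:
            pc = -pc
        metric = X @ pc
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    out = features.copy()
    out["metric"] = metric
    out.attrs["rule"] = rule
    return out


def maturity_tree(
    events: pd.DataFrame,
    label_col: str = "label",
    feature_cols: tuple[str, str] = ("extent", "esr"),
    max_splits: int = 4,
    folds: int = 5,
    seed: int = 0,
) -> tuple[DecisionTreeClassifier, float, dict]:
    """Coarse decision tree classifying events as immature vs mature.

    Limited to ``max_splits`` splits (max_leaf_nodes = max_splits + 1);
    accuracy is stratified k-fold cross-validated. Also returns per-class
    marginal histograms of both features.
    """
    labels = events[label_col]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need both classes present")
    counts = labels.value_counts()
    if counts.min() < 20:
        raise ValueError("need at least 20 events per class")
    X = events[list(feature_cols)].to_numpy(dtype=float)
    y = labels.to_numpy()
    tree = DecisionTreeClassifier(max_leaf_nodes=max_splits + 1, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = float(cross_val_score(tree, X, y, cv=cv, scoring="accuracy").mean())
    tree.fit(X, y)
    marginals = {}
    for feat in feature_cols:
        v = events[feat].to_numpy(dtype=float)
        edges = np.histogram_bin_edges(v, bins=20)
        marginals[feat] = {
            cls: np.histogram(v[y == cls], bins=edges, density=True)[0] for cls in classes
        }
        marginals[feat]["edges"] = edges
    return tree, acc, marginals
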