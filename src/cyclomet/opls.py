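"""Two-class OPLS-DA with cross-validated Q², VIP scores and S-plots.

Orthogonal projections to latent structures discriminant analysis
separates class-predictive variation in X (a single predictive
component for a binary response) from class-orthogonal variation,
removed iteratively before the predictive regression. The decomposition
follows the standard O-PLS algorithm: with y the centered ±1 class
coding,

    w  ∝ Xᵀy,  t = Xw,  p = Xᵀt/tᵀt
    w_o ∝ p − (wᵀp)w,  t_o = Xw_o,  p_o = Xᵀt_o/t_oᵀt_o,
    X ← X − t_o p_oᵀ          (repeated n_orth times)

Model quality is summarized by R²X (fraction of X sum of squares
captured by predictive plus orthogonal components), R²Y (training fit
of y) and the cross-validated prediction statistic Q² = 1 − PRESS/SS.
Following common metabolomics practice, Q² > 0.4 marks a valid model
and Q² > 0.7 a highly significant one; both boundaries are strict.

VIP (variable importance in projection) is computed from the predictive
component only — orthogonal variation is y-uncorrelated by construction
— which for a single component reduces to VIP_j = sqrt(p)·|w_j| with
the usual normalization mean(VIP²) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OplsModel",
    "fit_oplsda",
    "cross_validate_q2",
    "vip_scores",
    "s_plot",
    "classify_model",
    "ValidationLedger",
    "validate_subset",
    "permutation_q2",
]

_EPS = 1e-12

Q2_VALID = 0.4
Q2_HIGH = 0.7
VIP_SIGNIFICANT = 0.7


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    """Two-level labels -> ±1 (first sorted level = -1)."""
    y = np.asarray(y)
    levels = tuple(sorted(pd.unique(y)))
    if len(levels) != 2:
        raise ValueError(f"need exactly two classes, got {levels}")
    coded = np.where(y == levels[0], -1.0, 1.0)
    return coded, levels


@dataclass
class OplsModel:
    """A fitted two-class OPLS-DA model."""

    w: np.ndarray  # predictive weights, unit norm (p,)
    p_pred: np.ndarray  # predictive loadings (p,)
    t_pred: np.ndarray  # predictive scores on training data (n,)
    c: float  # inner regression coefficient y ~ t
    w_orth: np.ndarray  # (k, p) orthogonal weights, unit norm each
    p_orth: np.ndarray  # (k, p) orthogonal loadings
    t_orth: np.ndarray  # (k, n) orthogonal scores
    x_mean: np.ndarray
    y_mean: float
    levels: tuple
    r2x: float
    r2y: float
    n_samples: int
    n_features: int

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[0]

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and (first) orthogonal scores for new samples."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        t_orth_first = np.zeros(Xc.shape[0])
        for k in range(self.n_orth):
            t_o = Xc @ self.w_orth[k]
            if k == 0:
                t_orth_first = t_o
            Xc = Xc - np.outer(t_o, self.p_orth[k])
        return Xc @ self.w, t_orth_first

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X)
        return t * self.c + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels (decision threshold at the coded midpoint)."""
        yhat = self.decision_function(X)
        return np.where(yhat < 0.0, self.levels[0], self.levels[1])


def fit_oplsda(X, y, n_orth: int = 1) -> OplsModel:
    """Fit two-class OPLS-DA; deterministic (no randomness).

    ``X`` is a samples x features matrix (already scaled as desired;
    columns are additionally mean-centered internally so held-out
    samples can be projected), ``y`` holds two class labels, ``n_orth``
    the number of orthogonal components to strip before the predictive
    regression. Requires n >= 4 and 0 <= n_orth <= n-3.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    if n_orth < 0 or n_orth >= n - 2:
        raise ValueError(f"n_orth must be in [0, {n - 3}] for n={n}")
    coded, levels = _encode_labels(y)
    y_mean = float(coded.mean())
    yc = coded - y_mean
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    ss_x_total = float((Xc**2).sum())

    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm < _EPS:
        raise ValueError("X carries no covariance with y; cannot fit")
    w /= norm

    w_orth, p_orth, t_orth = [], [], []
    ss_x_orth = 0.0
    Xd = Xc
    for _ in range(n_orth):
        t = Xd @ w
        p_load = Xd.T @ t / max(t @ t, _EPS)
        wo = p_load - (w @ p_load) * w
        wo_norm = np.linalg.norm(wo)
        if wo_norm < 1e-10:
            break  # no orthogonal variation left
        wo /= wo_norm
        to = Xd @ wo
        po = Xd.T @ to / max(to @ to, _EPS)
        Xd = Xd - np.outer(to, po)
        w_orth.append(wo)
        p_orth.append(po)
        t_orth.append(to)
        ss_x_orth += float((to @ to) * (po @ po))

    t = Xd @ w
    tt = float(t @ t)
    p_pred = Xd.T @ t / max(tt, _EPS)
    c = float(yc @ t / max(tt, _EPS))
    resid = yc - c * t
    ss_y = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / max(ss_y, _EPS)
    r2x = (ss_x_orth + tt * float(p_pred @ p_pred)) / max(ss_x_total, _EPS)

    k = len(w_orth)
    return OplsModel(
        w=w,
        p_pred=p_pred,
        t_pred=t,
        c=c,
        w_orth=np.array(w_orth).reshape(k, p),
        p_orth=np.array(p_orth).reshape(k, p),
        t_orth=np.array(t_orth).reshape(k, n),
        x_mean=x_mean,
        y_mean=y_mean,
        levels=levels,
        r2x=float(r2x),
        r2y=float(r2y),
        n_samples=n,
        n_features=p,
    )


def _stratified_folds(coded: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment, round-robin within class after a seeded shuffle.

    Guarantees every fold's training set keeps both classes provided
    ``folds`` <= the smaller class count.
    """
    n = coded.size
    counts = {lv: int((coded == lv).sum()) for lv in (-1.0, 1.0)}
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n]")
    if folds > min(counts.values()):
        raise ValueError(
            f"cannot stratify {folds} folds with class counts {tuple(counts.values())}"
        )
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    for lv in (-1.0, 1.0):
        idx = np.flatnonzero(coded == lv)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validate_q2(X, y, n_orth: int = 1, folds: int = 7, seed: int = 0) -> float:
    """Cross-validated prediction statistic Q² = 1 − PRESS/SS.

    Stratified k-fold (default 7); PRESS accumulates squared prediction
    errors of held-out samples against the ±1 coded response; SS is the
    total sum of squares of the coded response about its global mean.
    Fold assignment is a deterministic function of the seed.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    coded, _ = _encode_labels(y)
    assign = _stratified_folds(coded, folds, seed)
    press = 0.0
    for f in range(folds):
        test = assign == f
        model = fit_oplsda(X[~test], coded[~test], n_orth=n_orth)
        yhat = model.decision_function(X[test])
        press += float(((coded[test] - yhat) ** 2).sum())
    ss = float(((coded - coded.mean()) ** 2).sum())
    return 1.0 - press / ss


def vip_scores(model: OplsModel, mz=None, feature_ids=None) -> pd.DataFrame:
    """VIP per feature from the predictive component, with rank order.

    Normalization: sum(VIP²) = number of features. Ranks sort VIP
    descending, breaking ties by feature m/z ascending then feature id.
    Returns a DataFrame indexed by feature id with columns vip, mz,
    rank, sorted by rank.
    """
    p = model.n_features
    vip = np.sqrt(p) * np.abs(model.w)
    ids = list(feature_ids) if feature_ids is not None else list(range(p))
    mz_col = np.asarray(mz, dtype=float) if mz is not None else np.full(p, np.nan)
    df = pd.DataFrame({"vip": vip, "mz": mz_col}, index=pd.Index(ids, name="feature_id"))
    df = df.sort_values(["vip", "mz", "feature_id"], ascending=[False, True, True], kind="stable")
    df["rank"] = np.arange(1, p + 1)
    return df


def s_plot(model: OplsModel, X, feature_ids=None) -> pd.DataFrame:
    """S-plot coordinates: p1 = cov(t, x_j), pcorr1 = corr(t, x_j).

    Computed against the centered input matrix (before orthogonal
    deflation). Zero-variance features get pcorr1 = 0 and a flag.
    Output sorted by p1 ascending.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    n = X.shape[0]
    t = model.t_pred
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    p1 = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    constant = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr = np.where(constant, 0.0, p1 / (np.where(constant, 1.0, sx) * st))
    ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[1]))
    df = pd.DataFrame(
        {"p1": p1, "pcorr1": pcorr, "zero_variance": constant},
        index=pd.Index(ids, name="feature_id"),
    )
    return df.sort_values("p1", kind="stable")


def classify_model(q2: float) -> str:
    """Verdict from Q²: invalid (≤0.4), valid (≤0.7), highly significant (>0.7)."""
    if q2 > Q2_HIGH:
        return "highly significant"
    if q2 > Q2_VALID:
        return "valid"
    return "invalid"


@dataclass
class ValidationLedger:
    """Full / include-top-N / exclude-top-N model summaries."""

    rows: pd.DataFrame  # model, n_features, r2x, r2y, q2, conditions, verdict
    useful_subset: bool

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write("".join(f"# {line}\n" for line in header_comment.splitlines()))
            self.rows.to_csv(fh, index=False)


def _model_row(label, X, y, n_orth, folds, seed, conditions) -> dict:
    model = fit_oplsda(X, y, n_orth=n_orth)
    q2 = cross_validate_q2(X, y, n_orth=n_orth, folds=folds, seed=seed)
    return {
        "model": label,
        "n_features": X.shape[1],
        "r2x": round(model.r2x, 6),
        "r2y": round(model.r2y, 6),
        "q2": round(q2, 6),
        "conditions": conditions,
        "verdict": classify_model(q2),
    }


def validate_subset(
    X,
    y,
    ranking: pd.DataFrame,
    top_n: int,
    n_orth: int = 1,
    folds: int = 7,
    seed: int = 0,
    conditions: str = "",
) -> ValidationLedger:
    """The parallel include/exclude-significant-features validation.

    Fits three models — all features, only the top-N VIP features, and
    everything except the top-N — and cross-validates each. The feature
    subset is declared useful when the include-only model is at least
    valid (Q² > 0.4) while the exclude model is invalid (Q² ≤ 0.4):
    the prioritized features then carry the class difference and nothing
    informative is left behind.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    p = X.shape[1]
    if not 0 < top_n < p:
        raise ValueError(f"top_n must be in (0, {p})")
    top = list(ranking.index[:top_n])
    rest = [c for c in X.columns if c not in set(top)]
    rows = [
        _model_row("full", X, y, n_orth, folds, seed, conditions),
        _model_row("include_top_vip", X[top], y, n_orth, folds, seed,
                   f"{conditions} (including top {top_n} VIP)".strip()),
        _model_row("exclude_top_vip", X[rest], y, n_orth, folds, seed,
                   f"{conditions} (excluding top {top_n} VIP)".strip()),
    ]
    df = pd.DataFrame(rows)
    include_ok = df.loc[1, "q2"] > Q2_VALID
    exclude_fails = df.loc[2, "q2"] <= Q2_VALID
    return ValidationLedger(rows=df, useful_subset=bool(include_ok and exclude_fails))


def permutation_q2(
    X, y, n_perm: int = 20, n_orth: int = 1, folds: int = 7, seed: int = 0
) -> dict:
    """Null Q² distribution under label permutation (overfit diagnostic).

    Returns the permuted-label Q² values with their median and 95th
    percentile; an observed Q² above the 95th percentile indicates
    class structure beyond chance.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    values = []
    for i in range(n_perm):
        perm = rng.permutation(y.size)
        values.append(cross_validate_q2(X, y[perm], n_orth=n_orth, folds=folds, seed=seed + i + 1))
    values = np.array(values)
    return {
        "values": values,
        "median": float(np.median(values)),
        "p95": float(np.quantile(values, 0.95)),
    }
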