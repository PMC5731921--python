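"""Biomarker performance statistics.

Two-group Mann-Whitney rank tests (exact enumeration at small n), ROC
curves with DeLong confidence intervals and the Youden optimal cutoff,
inter-peptide concordance within proteins, ridge-stabilized logistic
panel models, and risk stratification of the cancer group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

EXACT_N_MAX = 12  # exact enumeration up to this combined sample size


# ---------------------------------------------------------------- rank test

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a (midrank tie handling)."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def rank_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group a, P).

    P is by exhaustive enumeration over all group labelings when
    n_a + n_b <= 12, and by the tie-corrected normal approximation
    otherwise. Two-sided exact P counts labelings at least as far from
    the null mean n_a*n_b/2 as the observed U.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one non-missing value")
    u_obs = _u_statistic(a, b)
    n_a, n_b = a.size, b.size
    if n_a + n_b <= EXACT_N_MAX:
        mu = n_a * n_b / 2.0
        # U depends on the labeling only through the rank sum of group a,
        # so ranks are computed once and summed per labeling
        ranks = sps.rankdata(np.concatenate([a, b]))
        offset = n_a * (n_a + 1) / 2.0
        count = total = 0
        for subset in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(subset)].sum() - offset
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------- ROC

@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float          # after orientation (>= 0.5 unless degenerate)
    auc_raw: float      # higher-score = positive, as given
    ci_low: float
    ci_high: float
    flipped: bool


def _auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC for one marker."""
    def psi(x, y):
        return np.where(x > y, 1.0, np.where(x == y, 0.5, 0.0))

    m, n = pos.size, neg.size
    v10 = np.array([psi(x, neg).mean() for x in pos])
    v01 = np.array([psi(pos, y).mean() for y in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc(scores, labels, orient: bool = True) -> RocResult:
    """ROC curve, trapezoidal AUC and a 95% DeLong confidence interval.

    ``labels`` are binary with 1 = positive class (cancer). With
    ``orient=True`` (the default) scores are negated when the raw AUC is
    below 0.5, so the reported curve always reads higher-score = positive;
    the flip is recorded.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc_raw = _auc_trapezoid(fpr, tpr)
    flipped = False
    if orient and auc_raw < 0.5:
        flipped = True
        fpr, tpr, thr = _sk_roc_curve(y, -s)
        s_used = -s
    else:
        s_used = s
    auc = _auc_trapezoid(fpr, tpr)
    var = _delong_variance(s_used[y == 1], s_used[y == 0])
    z = 1.959963984540054
    if 0.0 < auc < 1.0 and var > 0.0:
        # logit-scale interval: much better small-sample coverage than
        # the plain Wald interval, which undercovers at n ~ 20
        se_logit = math.sqrt(var) / (auc * (1.0 - auc))
        logit = math.log(auc / (1.0 - auc))
        lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    else:  # degenerate AUC: clipped Wald fallback
        half = z * math.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return RocResult(fpr, tpr, thr, auc, auc_raw, lo, hi, flipped)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_sum: float
    degenerate: bool  # no threshold beats sensitivity + specificity = 1


def optimal_cutoff(curve: RocResult) -> CutoffResult:
    """Threshold maximizing sensitivity + specificity (Youden), ties
    broken toward higher specificity (a biopsy-sparing preference)."""
    sens = curve.tpr
    spec = 1.0 - curve.fpr
    total = sens + spec
    best = np.max(total)
    candidates = np.flatnonzero(np.isclose(total, best))
    # ties -> highest specificity
    i = candidates[np.argmax(spec[candidates])]
    return CutoffResult(
        cutoff=float(curve.thresholds[i]),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        youden_sum=float(best),
        degenerate=bool(best <= 1.0 + 1e-12),
    )


# -------------------------------------------------------------- concordance

@dataclass(frozen=True)
class ConcordancePair:
    peptide_a: str
    peptide_b: str
    r_squared: float | None
    n_used: int
    discordant_candidate: bool
    skip_reason: str | None = None


@dataclass(frozen=True)
class ConcordanceReport:
    protein: str
    pairs: tuple[ConcordancePair, ...]


def concordance(
    matrix: pd.DataFrame,
    protein_map: dict[str, str],
    min_n: int = 3,
    discordant_r2: float = 0.5,
) -> list[ConcordanceReport]:
    """Pearson R^2 between surrogate peptides of the same protein.

    Uses pairwise-complete samples; pairs with fewer than ``min_n``
    complete samples or a constant column are skipped with a reason.
    Pairs with R^2 below ``discordant_r2`` are marked as discordance
    candidates (possible unknown modification on one peptide).
    """
    by_protein: dict[str, list[str]] = {}
    for pep in matrix.columns:
        prot = protein_map.get(pep)
        if prot is not None:
            by_protein.setdefault(prot, []).append(pep)

    reports = []
    for prot, peps in sorted(by_protein.items()):
        pairs = []
        for pa, pb in itertools.combinations(peps, 2):
            sub = matrix[[pa, pb]].dropna()
            n = len(sub)
            if n < min_n:
                pairs.append(ConcordancePair(pa, pb, None, n, False,
                                             f"only {n} pairwise-complete samples"))
                continue
            if sub[pa].nunique() < 2 or sub[pb].nunique() < 2:
                pairs.append(ConcordancePair(pa, pb, None, n, False, "zero variance"))
                continue
            r, _ = sps.pearsonr(sub[pa], sub[pb])
            r2 = float(r * r)
            pairs.append(ConcordancePair(pa, pb, r2, n, r2 < discordant_r2))
        if pairs:
            reports.append(ConcordanceReport(prot, tuple(pairs)))
    return reports


# -------------------------------------------------------------- panel model

@dataclass(frozen=True)
class PanelModel:
    members: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    scores: pd.Series        # linear predictor per retained sample
    auc: float
    p_value: float
    n_used: int
    n_dropped: int


def fit_panel(
    matrix: pd.DataFrame,
    labels: pd.Series,
    members: list[str],
    ridge_lambda: float = 1e-4,
) -> PanelModel:
    """Logistic combination of a peptide subset.

    Rows with any missing member value are dropped. A small L2 (ridge)
    penalty keeps the maximum-likelihood fit finite under perfect
    separation, which is routine at cohort sizes of ~20. The panel score
    is the linear predictor; its AUC and two-sided rank-test P against
    the class labels summarize panel performance on the fitted data.
    """
    sub = matrix[list(members)].dropna()
    y = labels.loc[sub.index].astype(int)
    n_dropped = len(matrix) - len(sub)
    if y.nunique() < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class after row drops")
    X = sub.to_numpy(dtype=float)
    model = LogisticRegression(C=1.0 / ridge_lambda, max_iter=10_000)  # L2 default
    model.fit(X, y.to_numpy())
    lin = X @ model.coef_[0] + model.intercept_[0]
    scores = pd.Series(lin, index=sub.index, name="panel_score")
    curve = roc(lin, y.to_numpy(), orient=False)
    _, p = rank_test(lin[y.to_numpy() == 1], lin[y.to_numpy() == 0])
    return PanelModel(
        members=tuple(members),
        coefficients=dict(zip(members, model.coef_[0].tolist())),
        intercept=float(model.intercept_[0]),
        scores=scores,
        auc=curve.auc_raw,
        p_value=p,
        n_used=len(sub),
        n_dropped=n_dropped,
    )


def search_panels(
    matrix: pd.DataFrame,
    labels: pd.Series,
    candidates: list[str] | None = None,
    max_size: int = 5,
    ridge_lambda: float = 1e-4,
) -> list[PanelModel]:
    """Exhaustive logistic-panel search over subsets up to ``max_size``.

    Returns fits sorted best-first by AUC (ties: smaller panel, then
    lower P). Training-set AUCs at small n overfit; treat the ranking as
    hypothesis generation, not validated performance.
    """
    cands = list(candidates) if candidates is not None else list(matrix.columns)
    fits = []
    for k in range(1, max_size + 1):
        for members in itertools.combinations(cands, k):
            try:
                fits.append(fit_panel(matrix, labels, list(members), ridge_lambda))
            except ValueError:
                continue
    fits.sort(key=lambda m: (-m.auc, len(m.members), m.p_value))
    return fits


# ------------------------------------------------------------ stratification

def stratify(
    matrix: pd.DataFrame, significance: pd.Series
) -> pd.DataFrame:
    """Rank-test P per peptide between low-grade and significant cancers.

    ``significance`` holds 'low_grade' / 'significant' per sample
    (samples labelled otherwise are ignored). Returns a table of U, P and
    the group sizes used per peptide.
    """
    sig = significance[significance.isin(["low_grade", "significant"])]
    if (sig == "low_grade").sum() == 0 or (sig == "significant").sum() == 0:
        raise ValueError("both strata must be non-empty")
    rows = []
    for pep in matrix.columns:
        vals = matrix.loc[sig.index, pep]
        lo = vals[sig == "low_grade"].dropna()
        hi = vals[sig == "significant"].dropna()
        if lo.empty or hi.empty:
            rows.append({"peptide": pep, "U": np.nan, "p_value": np.nan,
                         "n_low_grade": len(lo), "n_significant": len(hi)})
            continue
        u, p = rank_test(hi, lo)
        rows.append({"peptide": pep, "U": u, "p_value": p,
                     "n_low_grade": len(lo), "n_significant": len(hi)})
    return pd.DataFrame(rows).set_index("peptide")


def bh_adjust(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted P values (supplementary column; the
    primary per-peptide report uses raw P)."""
    ok = p_values.dropna()
    adj = sps.false_discovery_control(ok.to_numpy(), method="bh")
    out = pd.Series(np.nan, index=p_values.index, name="p_bh")
    out.loc[ok.index] = adj
    return out
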