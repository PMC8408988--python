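"""Transcriptional deficiency signature: differential expression, survival
screening, lasso reduction and the prognostic-score equations.

The signature is derived in three stages mirroring how a transcriptional
surrogate of genomic HR deficiency is usually built:

1. **Differential expression** between HR-deficient and HR-proficient
   tumours on raw counts (negative-binomial Wald test with a trend-shrunk
   method-of-moments dispersion; median-of-ratios library normalisation);
   genes pass at FDR <= 0.05 and fold change >= 2 or <= 1/2.
2. **Univariate Cox screening** of each differential gene's log expression
   against the failure-free interval (FFI).
3. **Lasso-logistic reduction** predicting HRD status from the surviving
   candidates (cross-validated penalty, 1-SE rule), keeping each selected
   gene together with its univariate hazard ratio and direction.

Per-sample prognostic scores are then

    PS_i = sum_j Exp_ij / HR_j          (separately over up / down factors)
    HRDPS_i = PS_i,up - PS_i,down

where Exp is log-transformed expression and HR_j the univariate hazard
ratio of factor j.  Up-regulated factors must be protective (HR < 1) and
down-regulated factors must be risk factors (HR > 1); factors violating
this consistency are excluded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .immune import call_is_positive
from .stats import bh_adjust

DEFICIENT, PROFICIENT = "HR-deficient", "HR-proficient"


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample")
    ratios = log_counts[usable] - log_geo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def differential_expression(
    counts: pd.DataFrame,
    labels: pd.Series,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene deficient-vs-proficient differential expression on counts.

    ``counts``: integer gene x sample matrix.  ``labels``: per-sample
    group, either the status strings or booleans (True = deficient).
    Returns a table with log2 fold change (pseudocount 1), Wald p, BH FDR
    and the DEG flag.  All-zero genes are excluded.
    """
    labels = labels.loc[counts.columns]
    if labels.dtype == bool:
        deficient = labels.to_numpy()
    else:
        deficient = (labels == DEFICIENT).to_numpy()
        unknown = set(labels.unique()) - {DEFICIENT, PROFICIENT}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
    n1, n2 = int(deficient.sum()), int((~deficient).sum())
    if n1 < 3 or n2 < 3:
        raise ValueError("differential expression needs >= 3 samples per group")
    X = counts.to_numpy()
    if not np.issubdtype(X.dtype, np.integer):
        if np.any(X != np.floor(X)):
            raise ValueError(
                "counts must be integers; a log-expression matrix is the wrong input here"
            )
        X = X.astype(np.int64)

    expressed = X.sum(axis=1) > 0
    X = X[expressed].astype(float)
    genes = counts.index[expressed]

    sf = _size_factors(X)
    q = X / sf  # normalised counts

    m1 = q[:, deficient].mean(axis=1)
    m2 = q[:, ~deficient].mean(axis=1)
    mu = q.mean(axis=1)

    v1 = q[:, deficient].var(axis=1, ddof=1)
    v2 = q[:, ~deficient].var(axis=1, ddof=1)
    v_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (v_pooled - mu) / mu**2
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, np.nan)

    # mean-dispersion trend alpha(mu) = a0 + a1/mu, fit on positive estimates
    ok = np.isfinite(alpha_raw) & (alpha_raw > 0) & (mu > 0)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha_raw[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    else:
        a0, a1 = 0.05, 1.0
    alpha_trend = a0 + a1 / np.maximum(mu, 1e-8)

    # shrink gene-wise estimates toward the trend (geometric mean in log space)
    alpha_gene = np.where(ok, np.maximum(alpha_raw, 1e-8), alpha_trend)
    alpha = np.exp(0.5 * (np.log(alpha_gene) + np.log(alpha_trend)))

    lfc = np.log2((m1 + 1.0) / (m2 + 1.0))

    inv_sf_1 = np.mean(1.0 / sf[deficient])
    inv_sf_2 = np.mean(1.0 / sf[~deficient])
    var_m1 = (m1 * inv_sf_1 + alpha * m1**2) / n1
    var_m2 = (m2 * inv_sf_2 + alpha * m2**2) / n2
    se_lfc = np.sqrt(var_m1 / (m1 + 1.0) ** 2 + var_m2 / (m2 + 1.0) ** 2) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_lfc > 0, lfc / se_lfc, 0.0)
    p = 2 * sps.norm.sf(np.abs(z))
    fdr = bh_adjust(p)

    lfc_cut = np.log2(fc_threshold)
    deg = (fdr <= fdr_threshold) & (np.abs(lfc) >= lfc_cut)

    return pd.DataFrame(
        {
            "base_mean": mu,
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "deg": deg,
        },
        index=genes,
    )


# ---------------------------------------------------------------------------
# Univariate Cox screening
# ---------------------------------------------------------------------------

def cox_screen(
    log_expression: pd.DataFrame,
    times: pd.Series,
    events: pd.Series,
    candidate_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Univariate Cox fit of survival on each gene's log expression.

    Returns hazard ratio (per log-expression unit), coefficient and Wald
    p per gene; constant or non-converging genes are dropped with a
    warning.  Requires at least 10 events.
    """
    from lifelines import CoxPHFitter

    if candidate_genes is None:
        candidate_genes = list(log_expression.index)
    samples = log_expression.columns
    times = times.loc[samples]
    events = events.loc[samples]
    if int(events.sum()) < 10:
        raise ValueError("univariate Cox screening requires at least 10 events")
    base = pd.DataFrame({"time": times.to_numpy(dtype=float),
                         "event": events.to_numpy(dtype=int)}, index=samples)
    rows = []
    dropped = []
    for gene in candidate_genes:
        expr = log_expression.loc[gene]
        if expr.nunique() <= 1:
            dropped.append(gene)
            continue
        df = base.copy()
        df["x"] = expr.to_numpy(dtype=float)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            dropped.append(gene)
            continue
        s = cph.summary.loc["x"]
        rows.append(
            {
                "gene": gene,
                "coef": float(s["coef"]),
                "hr": float(s["exp(coef)"]),
                "p": float(s["p"]),
            }
        )
    if dropped:
        warnings.warn(f"cox screen: dropped {len(dropped)} gene(s) (constant or non-converging)")
    return pd.DataFrame(rows, columns=["gene", "coef", "hr", "p"]).set_index("gene")


# ---------------------------------------------------------------------------
# Signature container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureFactor:
    gene: str
    direction: str  # "up" or "down" in HR-deficient tumours
    hazard_ratio: float


@dataclass
class HrdSignature:
    """Selected prognostic factors with direction and univariate hazard
    ratio; up factors are protective (HR < 1), down factors risk (HR > 1)."""

    factors: list[SignatureFactor]

    def __post_init__(self) -> None:
        for f in self.factors:
            if f.hazard_ratio <= 0:
                raise ValueError(f"factor {f.gene}: hazard ratio must be > 0")
            if f.direction not in ("up", "down"):
                raise ValueError(f"factor {f.gene}: direction must be 'up' or 'down'")
            if f.direction == "up" and f.hazard_ratio >= 1:
                raise ValueError(f"up factor {f.gene} must have HR < 1")
            if f.direction == "down" and f.hazard_ratio <= 1:
                raise ValueError(f"down factor {f.gene} must have HR > 1")

    @property
    def genes(self) -> list[str]:
        return [f.gene for f in self.factors]

    def by_direction(self, direction: str) -> list[SignatureFactor]:
        return [f for f in self.factors if f.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene": f.gene, "direction": f.direction, "hazard_ratio": f.hazard_ratio}
                for f in self.factors
            ]
        )

    def to_json(self) -> str:
        return json.dumps(self.to_frame().to_dict(orient="records"), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HrdSignature":
        return cls(
            [
                SignatureFactor(d["gene"], d["direction"], float(d["hazard_ratio"]))
                for d in json.loads(text)
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HrdSignature":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                SignatureFactor(r.gene, r.direction, float(r.hazard_ratio))
                for r in df.itertuples()
            ]
        )


# ---------------------------------------------------------------------------
# Lasso reduction
# ---------------------------------------------------------------------------

def _cv_l1_logistic(
    Z: np.ndarray, y: np.ndarray, cs: np.ndarray, n_folds: int, seed: int
) -> float:
    """Cross-validated L1 path; 1-SE rule (the strongest penalty whose mean
    loss is within one standard error of the best).

    The loss is the cross-validated misclassification error.  Under a
    strong planted signal the deviance keeps improving as probabilities
    sharpen, so a deviance-based 1-SE rule admits many noise genes; the
    classification-error curve flattens once the true support is in the
    model, which is what redundancy removal needs.
    """
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    means, sems = [], []
    for c in cs:
        losses = []
        for tr, te in cv.split(Z, y):
            clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=c, random_state=0)
            clf.fit(Z[tr], y[tr])
            losses.append(1.0 - clf.score(Z[te], y[te]))
        losses = np.asarray(losses)
        means.append(losses.mean())
        sems.append(losses.std(ddof=1) / np.sqrt(len(losses)))
    means = np.asarray(means)
    best = int(np.argmin(means))
    limit = means[best] + sems[best]
    # cs ascending: smaller C = stronger penalty; pick the smallest C within 1 SE
    for i in range(len(cs)):
        if means[i] <= limit:
            return float(cs[i])
    return float(cs[best])


def lasso_reduce(
    log_expression: pd.DataFrame,
    hrd_labels: pd.Series,
    univariate: pd.DataFrame,
    de_log2fc: pd.Series,
    cs: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> HrdSignature:
    """Reduce candidate genes to a signature by L1-penalised logistic
    regression on HRD status.

    ``log_expression``: candidate genes x samples.  ``univariate``: the
    :func:`cox_screen` table supplying each gene's hazard ratio.
    ``de_log2fc``: per-gene fold change fixing the direction (up iff > 0).
    Duplicate (identical) expression columns are collapsed to the first
    occurrence before fitting.  Genes violating the direction/HR
    consistency rule are excluded with a warning.
    """
    candidates = [g for g in log_expression.index if g in univariate.index]
    if len(candidates) < 2:
        raise ValueError("lasso reduction needs at least 2 candidate genes")
    X = log_expression.loc[candidates].T  # samples x genes
    # collapse exact duplicate columns (redundant factors)
    X = X.T.drop_duplicates().T
    candidates = list(X.columns)
    y = hrd_labels.loc[X.index]
    if y.dtype != bool:
        y = y == DEFICIENT
    y = y.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both HRD classes are required")

    Z = X.to_numpy(dtype=float)
    center = Z.mean(axis=0)
    scale = Z.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (Z - center) / scale

    if cs is None:
        cs = np.logspace(-2, 1, 12)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    c = _cv_l1_logistic(Z, y, np.asarray(cs, dtype=float), n_folds, seed) if n_folds >= 2 else 1.0
    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=c, random_state=0)
    clf.fit(Z, y)
    coef = clf.coef_[0]
    selected = [g for g, w in zip(candidates, coef) if w != 0.0]
    if not selected:
        raise ValueError(
            "lasso shrank every coefficient to zero; use a weaker penalty (larger C)"
        )

    factors = []
    for gene in selected:
        hr = float(univariate.loc[gene, "hr"])
        direction = "up" if float(de_log2fc.loc[gene]) > 0 else "down"
        consistent = (direction == "up" and hr < 1) or (direction == "down" and hr > 1)
        if not consistent:
            warnings.warn(
                f"gene {gene}: direction {direction} inconsistent with HR {hr:.3f}, excluded"
            )
            continue
        factors.append(SignatureFactor(gene, direction, hr))
    return HrdSignature(factors)


# ---------------------------------------------------------------------------
# Prognostic scores
# ---------------------------------------------------------------------------

def prognostic_score(log_expression: pd.DataFrame, signature: HrdSignature) -> pd.DataFrame:
    """Per-sample PS_up, PS_down and HRDPS = PS_up - PS_down.

    Each factor contributes its log expression divided by its univariate
    hazard ratio.  All signature genes must be present in the matrix.
    """
    missing = [g for g in signature.genes if g not in log_expression.index]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    samples = log_expression.columns
    ps_up = pd.Series(0.0, index=samples)
    ps_down = pd.Series(0.0, index=samples)
    for f in signature.factors:
        contrib = log_expression.loc[f.gene] / f.hazard_ratio
        if f.direction == "up":
            ps_up = ps_up + contrib
        else:
            ps_down = ps_down + contrib
    return pd.DataFrame(
        {"ps_up": ps_up, "ps_down": ps_down, "hrdps": ps_up - ps_down}
    )


def call_hrdps_positive(scores: pd.Series, rule: str | float = "median") -> pd.Series:
    """Positivity call on HRDPS: strictly above the cohort median by
    default, or above an arbitrary quantile when ``rule`` is a float."""
    if len(scores) < 4:
        raise ValueError("positivity call requires at least 4 samples")
    if rule == "median":
        return (scores > scores.median()).rename("hrdps_positive")
    return call_is_positive(scores, quantile=float(rule)).rename("hrdps_positive")


# ---------------------------------------------------------------------------
# Signature as a deficiency predictor
# ---------------------------------------------------------------------------

def evaluate_signature_as_hrd_predictor(
    log_expression: pd.DataFrame,
    signature: HrdSignature,
    hrd_labels: pd.Series,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of a lasso-logistic deficiency predictor built on the signature
    genes.  Returns (fpr, tpr, auc); AUC is trapezoidal."""
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import roc_curve

    missing = [g for g in signature.genes if g not in log_expression.index]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    y = hrd_labels.loc[log_expression.columns]
    if y.dtype != bool:
        y = y == DEFICIENT
    y = y.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes are required for a ROC curve")
    Z = log_expression.loc[signature.genes].T.to_numpy(dtype=float)
    center, scale = Z.mean(axis=0), Z.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=1.0, random_state=seed)
    clf.fit((Z - center) / scale, y)
    probs = clf.predict_proba((Z - center) / scale)[:, 1]
    fpr, tpr, _ = roc_curve(y, probs)
    return fpr, tpr, float(_auc(fpr, tpr))
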