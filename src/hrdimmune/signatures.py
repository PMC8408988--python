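"""Trinucleotide mutation spectra, signature-exposure fitting and an
HRDetect-style deficiency classifier.

Somatic single-base substitutions are tabulated into the canonical 96
trinucleotide channels (6 pyrimidine-strand substitution classes x 16
flanking-base contexts).  Per-sample exposures to a set of mutational
signatures are obtained by iterative forward selection with non-negative
least-squares refitting, mirroring the scheme popularised by
deconstructSigs: signatures are added greedily while the reconstruction
error of the normalised spectrum keeps improving, and weights below a
6% floor are discarded.

The module also computes the insertion/deletion ratio and provides a
lasso-logistic classifier over scar- and signature-derived features
(scar score, exposures of breast-cancer signatures, indel ratio) in the
spirit of HRDetect.  The published whole-exome HRDetect weights are not
redistributable, so the classifier is trained on cohorts with known
deficiency labels (see :func:`train_hrdetect`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical channel order: substitution class (pyrimidine convention),
#: then 5' base, then 3' base, e.g. "A[C>A]A".
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def mutation_channel(ref: str, alt: str, context: str) -> str | None:
    """Map one SNV to its 96-channel label, or None if unresolvable.

    ``context`` is the 3-mer centred on the reference base.  Purine
    reference alleles are reverse-complemented to the pyrimidine strand.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if len(context) != 3 or any(b not in COMPLEMENT for b in context):
        return None
    if context[1] != ref or alt not in COMPLEMENT:
        return None
    if ref in ("G", "A"):
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return label if label in _CHANNEL_INDEX else None


def build_spectrum(mutations: pd.DataFrame, sample_id: str | None = None) -> pd.Series:
    """96-channel trinucleotide spectrum of one sample's mutation table.

    Indels, multi-nucleotide variants and SNVs with unresolvable context
    are excluded (the number of dropped SNVs is logged).
    """
    counts = np.zeros(len(CHANNELS_96), dtype=np.int64)
    dropped = 0
    if not mutations.empty:
        for row in mutations.itertuples():
            ref, alt = str(row.ref), str(row.alt)
            if len(ref) != 1 or len(alt) != 1:
                continue  # indel / MNV: not part of the SNV spectrum
            channel = mutation_channel(ref, alt, str(row.trinucleotide_context))
            if channel is None:
                dropped += 1
                continue
            counts[_CHANNEL_INDEX[channel]] += 1
    if dropped:
        logger.info("spectrum: excluded %d SNVs with unresolvable context", dropped)
    name = sample_id
    if name is None and "sample" in mutations.columns and len(mutations):
        name = str(mutations["sample"].iloc[0])
    return pd.Series(counts, index=list(CHANNELS_96), name=name)


def build_spectra(mutations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample spectra (samples x 96) of a cohort mutation table."""
    specs = {
        sample: build_spectrum(sub, sample_id=sample)
        for sample, sub in mutations.groupby("sample", sort=True)
    }
    return pd.DataFrame(specs).T.reindex(columns=list(CHANNELS_96), fill_value=0)


# ---------------------------------------------------------------------------
# Packaged signature profiles (synthetic stand-ins)
# ---------------------------------------------------------------------------

def synthetic_signature_matrix() -> pd.DataFrame:
    """Five synthetic 96-channel signature profiles (columns sum to 1).

    These are constructed stand-ins that mimic qualitative features of the
    breast-cancer COSMIC signatures they are named after -- SBS1
    (C>T at NpCpG), SBS3 (near-flat), SBS6 and SBS20 (MMR-flavoured
    C>T / C>A enrichment) -- plus an exactly uniform "flat" column.  They
    are NOT the published COSMIC vectors; real matrices can be loaded with
    :func:`read_signature_matrix`.
    """
    idx = list(CHANNELS_96)
    n = len(idx)

    def class_of(ch: str) -> str:
        return ch[2:5]

    def five_prime(ch: str) -> str:
        return ch[0]

    def three_prime(ch: str) -> str:
        return ch[6]

    sbs1 = np.full(n, 0.12 / 80)
    for i, ch in enumerate(idx):
        if class_of(ch) == "C>T":
            sbs1[i] = (0.88 * 0.8 / 4) if three_prime(ch) == "G" else (0.88 * 0.2 / 12)

    class_mass = {"C>A": 0.18, "C>G": 0.12, "C>T": 0.19, "T>A": 0.13, "T>C": 0.21, "T>G": 0.17}
    ripple = 1.0 + 0.25 * np.cos(0.7 * np.arange(n))
    sbs3 = np.array([class_mass[class_of(ch)] / 16 for ch in idx]) * ripple
    sbs3 /= sbs3.sum()

    sbs6 = np.full(n, 0.20 / 64)
    for i, ch in enumerate(idx):
        if class_of(ch) == "C>T":
            sbs6[i] = (0.55 * 0.6 / 4) if five_prime(ch) == "G" else (0.55 * 0.4 / 12)
        elif class_of(ch) == "T>C":
            sbs6[i] = 0.25 / 16
    sbs6 /= sbs6.sum()

    sbs20 = np.full(n, 0.10 / 48)
    for i, ch in enumerate(idx):
        if class_of(ch) == "C>A":
            sbs20[i] = (0.40 * 0.7 / 4) if five_prime(ch) == "C" else (0.40 * 0.3 / 12)
        elif class_of(ch) == "C>T":
            sbs20[i] = 0.30 / 16
        elif class_of(ch) == "T>A":
            sbs20[i] = 0.20 / 16
    sbs20 /= sbs20.sum()

    flat = np.full(n, 1.0 / n)

    mat = pd.DataFrame(
        {"SBS1": sbs1, "SBS3": sbs3, "SBS6": sbs6, "SBS20": sbs20, "flat": flat},
        index=idx,
    )
    return mat / mat.sum(axis=0)


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a 96 x signatures TSV (row index = channel labels)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS_96) - set(mat.index)
    if missing:
        raise ValueError(f"signature matrix missing {len(missing)} channels")
    mat = mat.loc[list(CHANNELS_96)]
    return mat / mat.sum(axis=0)


# ---------------------------------------------------------------------------
# Exposure fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureExposures:
    sample_id: str | None
    weights: pd.Series  # per-signature weight in [0, 1]
    reconstruction_error: float

    def __getitem__(self, signature: str) -> float:
        return float(self.weights[signature])


def _nnls_fit(target: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, float]:
    w, err = nnls(matrix, target)
    return w, err


def fit_exposures(
    spectrum: pd.Series,
    signature_matrix: pd.DataFrame | None = None,
    drop_floor: float = 0.06,
    tol: float = 1e-3,
) -> SignatureExposures:
    """Fit per-sample signature exposures by greedy forward selection.

    The observed spectrum is normalised to sum 1; signatures are added one
    at a time, each step refitting all selected weights by non-negative
    least squares and keeping the candidate that most reduces the residual
    L2 error, until the improvement falls below ``tol``.  Weights below
    ``drop_floor`` are then zeroed, the remaining weights refit and
    rescaled against the pre-drop total.
    """
    if signature_matrix is None:
        signature_matrix = synthetic_signature_matrix()
    total_mut = float(spectrum.sum())
    if total_mut <= 0:
        raise ValueError("cannot fit exposures of an empty spectrum")
    v = spectrum.reindex(list(CHANNELS_96), fill_value=0).to_numpy(dtype=float)
    v = v / v.sum()
    M = signature_matrix.to_numpy(dtype=float)
    names = list(signature_matrix.columns)

    selected: list[int] = []
    best_err = float(np.linalg.norm(v))
    best_w = np.zeros(0)
    while len(selected) < len(names):
        step_best = None
        for j in range(len(names)):
            if j in selected:
                continue
            cols = selected + [j]
            w, err = _nnls_fit(v, M[:, cols])
            if step_best is None or err < step_best[1]:
                step_best = (cols, err, w)
        cols, err, w = step_best
        if best_err - err < tol and selected:
            break
        selected, best_err, best_w = cols, err, w
        if best_err < tol:
            break

    weights = np.zeros(len(names))
    weights[selected] = best_w
    total = weights.sum()
    if total > 1.0:  # tiny NNLS overshoot on noisy spectra
        weights /= total
        total = 1.0

    keep = [j for j in selected if weights[j] >= drop_floor]
    if keep and set(keep) != set(selected):
        w_keep, err_keep = _nnls_fit(v, M[:, keep])
        weights = np.zeros(len(names))
        weights[keep] = w_keep
        best_err = err_keep
        if weights.sum() > 0:
            weights *= min(total, 1.0) / weights.sum()
    elif not keep:
        weights = np.zeros(len(names))
        best_err = float(np.linalg.norm(v))

    return SignatureExposures(
        sample_id=spectrum.name,
        weights=pd.Series(weights, index=names),
        reconstruction_error=float(best_err),
    )


def fit_cohort_exposures(
    spectra: pd.DataFrame,
    signature_matrix: pd.DataFrame | None = None,
    drop_floor: float = 0.06,
) -> pd.DataFrame:
    """Exposures for every row (sample) of a spectra matrix; samples with
    empty spectra get all-zero exposures."""
    if signature_matrix is None:
        signature_matrix = synthetic_signature_matrix()
    rows = {}
    for sample, spec in spectra.iterrows():
        if spec.sum() <= 0:
            rows[sample] = pd.Series(0.0, index=signature_matrix.columns)
        else:
            rows[sample] = fit_exposures(spec, signature_matrix, drop_floor).weights
    return pd.DataFrame(rows).T


def is_sbs3_dominant(exposures: SignatureExposures | pd.Series, threshold: float = 0.3) -> bool:
    """Dominant SBS3 activity at the inclusive threshold."""
    weights = exposures.weights if isinstance(exposures, SignatureExposures) else exposures
    if "SBS3" not in weights.index:
        raise KeyError("SBS3 not among fitted signatures")
    return bool(weights["SBS3"] >= threshold)


# ---------------------------------------------------------------------------
# Indel ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelRatio:
    value: float
    n_insertions: int
    n_deletions: int
    denominator_zero: bool


def indel_ratio(mutations: pd.DataFrame) -> IndelRatio:
    """Insertion/deletion count ratio.

    With zero deletions the insertion count itself is returned, flagged
    ``denominator_zero`` (a guarded sentinel rather than infinity).
    """
    if mutations.empty:
        n_ins = n_del = 0
    else:
        ref_len = mutations["ref"].astype(str).str.len()
        alt_len = mutations["alt"].astype(str).str.len()
        n_ins = int((alt_len > ref_len).sum())
        n_del = int((alt_len < ref_len).sum())
    if n_del == 0:
        if n_ins > 0:
            warnings.warn("indel ratio: no deletions; returning insertion count, flagged")
        return IndelRatio(float(n_ins), n_ins, n_del, denominator_zero=True)
    return IndelRatio(n_ins / n_del, n_ins, n_del, denominator_zero=False)


# ---------------------------------------------------------------------------
# HRDetect-style lasso-logistic classifier
# ---------------------------------------------------------------------------

DEFAULT_HRDETECT_FEATURES = (
    "hrd_score",
    "SBS1",
    "SBS3",
    "SBS6",
    "SBS20",
    "indel_ratio",
)


@dataclass(frozen=True, eq=False)
class HrdetectModel:
    """Standardised lasso-logistic model over deficiency-related features."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("invalid model: scales must be > 0 and weights finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "HrdetectModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


def hrdetect_score(features, model: HrdetectModel) -> float:
    """Deficiency probability of one sample: logistic of the standardised
    linear predictor.  The conventional "high" call is >= 0.7."""
    if isinstance(features, pd.Series):
        features = features.to_dict()
    supplied = set(features)
    expected = set(model.feature_names)
    if supplied != expected:
        raise ValueError(
            f"feature mismatch: missing {sorted(expected - supplied)}, "
            f"unexpected {sorted(supplied - expected)}"
        )
    x = np.array([float(features[f]) for f in model.feature_names])
    z = model.intercept + np.dot(model.weights, (x - model.center) / model.scale)
    return float(expit(z))


def hrdetect_scores(features: pd.DataFrame, model: HrdetectModel) -> pd.Series:
    return pd.Series(
        {s: hrdetect_score(row, model) for s, row in features.iterrows()},
        name="hrdetect",
    )


def train_hrdetect(
    features: pd.DataFrame,
    labels: pd.Series,
    cs: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> HrdetectModel:
    """Train the lasso-logistic deficiency classifier.

    Features are standardised; the L1 strength is chosen by stratified
    cross-validated log-loss over a grid of inverse penalties.
    """
    labels = labels.loc[features.index].astype(int)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("training requires both deficient and proficient samples")
    X = features.to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    y = labels.to_numpy()

    if cs is None:
        cs = np.logspace(-2, 2, 15)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds >= 2:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        losses = []
        for c in cs:
            fold_losses = []
            for train_idx, test_idx in cv.split(Z, y):
                clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=c, random_state=0)
                clf.fit(Z[train_idx], y[train_idx])
                p = clf.predict_proba(Z[test_idx])[:, 1]
                fold_losses.append(log_loss(y[test_idx], p, labels=[0, 1]))
            losses.append(np.mean(fold_losses))
        best_c = float(cs[int(np.argmin(losses))])
    else:
        best_c = 1.0

    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=best_c, random_state=0)
    clf.fit(Z, y)
    return HrdetectModel(
        feature_names=tuple(features.columns),
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        center=center,
        scale=scale,
    )
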