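"""Single-sample immune activity scoring.

Gene-set activity is computed with a rank-based single-sample enrichment
statistic (the ssGSEA running-sum form): within each sample, genes are
ranked by expression, and a set's activity is the summed difference
between the weighted cumulative distribution of in-set genes (normalised
ranks raised to an exponent, 0.25 by default) and the unweighted
cumulative distribution of out-of-set genes.  Because the statistic only
uses ranks, it is invariant to any strictly increasing per-sample
transformation of the expression values.

Two immune-score (IS) definitions are offered: the sum of the activities
of a named collection of immune pathways, and the mean log expression of a
marker-gene list.  Within a cohort, samples in the top quartile of IS are
called IS-positive.

The bundled gene sets (:func:`synthetic_immune_sets`) are synthetic
placeholders named after interferon / checkpoint-blockade / effector-T
pathways; real analyses must supply curated sets (GMT format).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance label."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"gene set {name!r} has invalid gene identifiers")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path, provenance: str = "") -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated genes)."""
    from gseapy.parser import read_gmt as _read_gmt

    sets = _read_gmt(str(path))
    return GeneSetCollection({k: list(v) for k, v in sets.items()}, provenance or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.provenance or "na", *genes]) + "\n")


#: Immune pathways planted by the synthetic-cohort generator (15 genes each).
IMMUNE_PATHWAY_NAMES = (
    "INTERFERON_GAMMA_SIGNALLING",
    "PD_L_BLOCKADE",
    "CTLA4_PATHWAY",
    "CD28_COSTIMULATION",
    "NK_CYTOTOXICITY",
    "ANTIGEN_PROCESSING_PRESENTATION",
    "JAK_STAT_SIGNALLING",
    "IL2_STAT45_SIGNALLING",
    "CD8_EFFECTOR_T_CELLS",
)

IMMUNE_SET_SIZE = 15


def synthetic_immune_sets() -> GeneSetCollection:
    """Synthetic placeholder immune gene sets matching the generator's
    gene naming; stand-ins for curated immune-pathway collections."""
    sets = {
        name: [f"{name}_{i:02d}" for i in range(1, IMMUNE_SET_SIZE + 1)]
        for name in IMMUNE_PATHWAY_NAMES
    }
    return GeneSetCollection(sets, provenance="synthetic")


def synthetic_immune_markers(n: int = 10) -> list[str]:
    """Synthetic stand-in for a prognostic immune marker-gene list."""
    pool = synthetic_immune_sets().sets
    markers = pool["CD8_EFFECTOR_T_CELLS"][: n // 2]
    markers += pool["INTERFERON_GAMMA_SIGNALLING"][: n - len(markers)]
    return markers


# ---------------------------------------------------------------------------
# Single-sample enrichment
# ---------------------------------------------------------------------------

def _sample_activity(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment of one sample.

    ``order`` indexes genes from most to least expressed; ``in_set`` flags
    set membership per gene.
    """
    n = order.size
    members = in_set[order]
    n_in = int(members.sum())
    n_out = n - n_in
    if n_out == 0:
        # degenerate: the set is the whole universe, nothing to discriminate
        return 0.0
    weights = (np.arange(n, 0, -1) ** alpha).astype(float)  # rank weight, top gene largest
    w_in = np.where(members, weights, 0.0)
    denom_in = w_in.sum()
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum(~members) / n_out
    return float(np.sum(cdf_in - cdf_out))


def single_sample_activity(
    log_expression: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Activity matrix (gene sets x samples) by single-sample enrichment.

    Sets matching fewer than 2 genes of the expression matrix are skipped
    with a warning.  When ``normalize`` is set, all activities are divided
    by the global max-min range across the cohort.
    """
    if log_expression.empty:
        raise ValueError("expression matrix is empty")
    if log_expression.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    genes = log_expression.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}

    memberships: dict[str, np.ndarray] = {}
    for name, members in sets:
        matched = [gene_pos[g] for g in members if g in gene_pos]
        if len(matched) < 2:
            warnings.warn(f"gene set {name!r}: fewer than 2 genes matched, skipped")
            continue
        flag = np.zeros(len(genes), dtype=bool)
        flag[matched] = True
        memberships[name] = flag
    if not memberships:
        raise ValueError("no gene set matched the expression matrix")

    values = log_expression.to_numpy(dtype=float)
    activities = np.zeros((len(memberships), values.shape[1]))
    for s in range(values.shape[1]):
        # stable argsort on negated values: ties broken by gene order
        order = np.argsort(-values[:, s], kind="stable")
        for k, flag in enumerate(memberships.values()):
            activities[k, s] = _sample_activity(order, flag, alpha)

    out = pd.DataFrame(activities, index=list(memberships), columns=log_expression.columns)
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return out


# ---------------------------------------------------------------------------
# Immune scores
# ---------------------------------------------------------------------------

def immune_score_pathway(
    activities: pd.DataFrame, immune_set_names: list[str] | None = None
) -> pd.Series:
    """Per-sample immune score: the sum of the named pathway activities."""
    if immune_set_names is None:
        immune_set_names = list(activities.index)
    unknown = [n for n in immune_set_names if n not in activities.index]
    if unknown:
        raise KeyError(
            f"unknown gene set name(s) {unknown}; known: {list(activities.index)}"
        )
    return activities.loc[immune_set_names].sum(axis=0).rename("immune_score")


def immune_score_markers(
    log_expression: pd.DataFrame, marker_genes: list[str]
) -> pd.Series:
    """Per-sample immune score: mean log expression of matched markers."""
    matched = [g for g in marker_genes if g in log_expression.index]
    if not matched:
        raise KeyError(f"no marker gene matched the expression matrix: {marker_genes}")
    return log_expression.loc[matched].mean(axis=0).rename("immune_score")


def call_is_positive(scores: pd.Series, quantile: float = 0.75) -> pd.Series:
    """Top-quartile positivity: score strictly above the empirical
    quantile (linear-interpolation definition).  With all-tied scores no
    sample is positive."""
    if len(scores) < 4:
        raise ValueError("positivity call requires at least 4 samples")
    threshold = float(np.quantile(scores.to_numpy(dtype=float), quantile))
    return (scores > threshold).rename("is_positive")
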