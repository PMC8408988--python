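"""Genomic-scar scoring of allele-specific copy-number profiles.

Homologous-recombination deficient (HRD) tumours accumulate characteristic
structural lesions.  Three established scar counts are computed from an
allele-specific segmentation of the tumour genome:

* **LOH** — large (> 15 Mb) regions of loss of heterozygosity that do not
  span a whole chromosome;
* **ntAI** — allelic imbalances that extend to a telomere without crossing
  the centromere, above an 11-Mb size floor;
* **LST** — large-scale state transitions: breakpoints between adjacent
  segments of at least 10 Mb (after smoothing away segments below 3 Mb)
  separated by at most 3 Mb.

The scar score is the plain sum of the three counts.  HR status combines
the score (deficient at >= 42) with deleterious tumour BRCA1/2 mutations.
This module also calls BRCA1 promoter hypermethylation from array beta
values, maps methylation probes to promoters, and computes tumour mutation
burden (TMB).

All segment coordinates are 1-based inclusive (SEG convention); the length
of a segment is ``end - start + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MB, GenomeAnnotation

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]

#: Consequence labels treated as deleterious for BRCA1/2 status calls.
DELETERIOUS_CONSEQUENCES = frozenset(
    {"frameshift", "nonsense", "splice_site", "pathogenic_missense"}
)

#: Consequence labels counted as nonsynonymous for TMB.
NONSYNONYMOUS_CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "inframe_insertion",
        "inframe_deletion",
        "nonstop",
        "pathogenic_missense",
    }
)


@dataclass(frozen=True)
class ScarParams:
    """Size thresholds of the three scar definitions, in base pairs.

    The published scar constructions fix these at 15 Mb (LOH), 11 Mb
    (ntAI floor) and 10/3 Mb (LST segment minimum / smoothing and gap);
    they are exposed here because minor threshold variants circulate.
    """

    loh_min_length: int = 15 * MB
    tai_min_length: int = 11 * MB
    lst_min_segment: int = 10 * MB
    lst_smooth_below: int = 3 * MB
    lst_max_gap: int = 3 * MB


DEFAULT_SCAR_PARAMS = ScarParams()

HR_DEFICIENT = "HR-deficient"
HR_PROFICIENT = "HR-proficient"


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments of one sample.

    ``segments`` columns: chrom, start, end, total_cn, minor_cn.  Segments
    must be non-overlapping within a chromosome, with minor_cn <= total_cn.
    """

    sample_id: str
    segments: pd.DataFrame
    genome: GenomeAnnotation

    def __post_init__(self) -> None:
        seg = self.segments
        missing = set(SEGMENT_COLUMNS) - set(seg.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        seg = seg[SEGMENT_COLUMNS].copy()
        seg = seg.astype(
            {"chrom": str, "start": np.int64, "end": np.int64,
             "total_cn": np.int64, "minor_cn": np.int64}
        )
        if (seg["end"] < seg["start"]).any():
            bad = seg[seg["end"] < seg["start"]].iloc[0]
            raise ValueError(
                f"sample {self.sample_id}: segment end < start at "
                f"{bad.chrom}:{bad.start}-{bad.end}"
            )
        if (seg["total_cn"] < 0).any() or (seg["minor_cn"] < 0).any():
            raise ValueError(f"sample {self.sample_id}: negative copy number")
        if (seg["minor_cn"] > seg["total_cn"]).any():
            raise ValueError(f"sample {self.sample_id}: minor_cn exceeds total_cn")
        seg = seg.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in seg.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] <= sub["end"].to_numpy()[:-1]).any():
                raise ValueError(
                    f"sample {self.sample_id}: overlapping segments on {chrom}"
                )
            if chrom not in self.genome:
                raise ValueError(
                    f"sample {self.sample_id}: segment on unannotated chromosome {chrom}"
                )
        self.segments = seg

    @property
    def lengths(self) -> pd.Series:
        return self.segments["end"] - self.segments["start"] + 1


@dataclass(frozen=True)
class HrdScore:
    """The three scar counts and their sum."""

    loh_count: int
    tai_count: int
    lst_count: int

    @property
    def total(self) -> int:
        return self.loh_count + self.tai_count + self.lst_count


@dataclass(frozen=True)
class HrStatusCall:
    sample_id: str
    tbrca_mutated: bool
    hrd_score: HrdScore
    threshold: int
    status: str


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    probe: str
    beta: float | None
    silenced: bool | None
    missing: bool


def count_loh(profile: SegmentProfile, params: ScarParams = DEFAULT_SCAR_PARAMS) -> int:
    """Count LOH segments: minor allele lost, total >= 1 copy, length
    strictly above the size threshold, not spanning a whole chromosome."""
    seg = profile.segments
    n = 0
    for row in seg.itertuples():
        length = row.end - row.start + 1
        if row.minor_cn != 0 or row.total_cn < 1:
            continue
        if length <= params.loh_min_length:
            continue
        chrom = profile.genome[row.chrom]
        if row.start <= 1 and row.end >= chrom.length:
            continue  # whole-chromosome LOH is excluded
        n += 1
    return n


def count_tai(profile: SegmentProfile, params: ScarParams = DEFAULT_SCAR_PARAMS) -> int:
    """Count telomeric allelic imbalances: imbalanced segments that reach a
    chromosome end, do not cross the centromere, above the size floor."""
    n = 0
    for row in profile.segments.itertuples():
        if 2 * row.minor_cn == row.total_cn:
            continue  # balanced
        length = row.end - row.start + 1
        if length <= params.tai_min_length:
            continue
        chrom = profile.genome[row.chrom]
        touches_telomere = row.start <= 1 or row.end >= chrom.length
        if not touches_telomere:
            continue
        crosses_centromere = row.start < chrom.cen_start and row.end > chrom.cen_end
        if crosses_centromere:
            continue
        n += 1
    return n


def _arm_segments(profile: SegmentProfile) -> list[list[tuple[int, int, int, int]]]:
    """Split segments at the centromere into per-arm lists of
    (start, end, total_cn, minor_cn), ordered along the arm."""
    arms: list[list[tuple[int, int, int, int]]] = []
    for chrom, sub in profile.segments.groupby("chrom", sort=False):
        ann = profile.genome[chrom]
        p_arm, q_arm = [], []
        for row in sub.itertuples():
            # portion on the p arm (before the centromere)
            if row.start < ann.cen_start:
                p_arm.append(
                    (row.start, min(row.end, ann.cen_start - 1), row.total_cn, row.minor_cn)
                )
            # portion on the q arm (after the centromere)
            if row.end > ann.cen_end:
                q_arm.append(
                    (max(row.start, ann.cen_end + 1), row.end, row.total_cn, row.minor_cn)
                )
        arms.extend([arm for arm in (p_arm, q_arm) if arm])
    return arms


def _smooth_arm(
    arm: list[tuple[int, int, int, int]], params: ScarParams
) -> list[tuple[int, int, int, int]]:
    """Merge segments below the smoothing threshold into their larger
    neighbour (left neighbour on ties); isolated small segments are dropped.
    Adjacent same-state segments are then coalesced."""
    segs = list(arm)
    while True:
        lengths = [s[1] - s[0] + 1 for s in segs]
        small = [i for i, ln in enumerate(lengths) if ln < params.lst_smooth_below]
        if not small:
            break
        # smallest first; leftmost on ties
        i = min(small, key=lambda k: (lengths[k], k))
        if len(segs) == 1:
            return []
        left = i - 1 if i > 0 else None
        right = i + 1 if i < len(segs) - 1 else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            llen = lengths[left]
            rlen = lengths[right]
            target = left if llen >= rlen else right
        s, e, _, _ = segs[i]
        ts, te, tt, tm = segs[target]
        segs[target] = (min(ts, s), max(te, e), tt, tm)
        del segs[i]
    merged: list[tuple[int, int, int, int]] = []
    for s in segs:
        if merged and merged[-1][2:] == s[2:] and s[0] - merged[-1][1] - 1 == 0:
            merged[-1] = (merged[-1][0], s[1], s[2], s[3])
        else:
            merged.append(s)
    return merged


def count_lst(profile: SegmentProfile, params: ScarParams = DEFAULT_SCAR_PARAMS) -> int:
    """Count large-scale state transitions per chromosome arm.

    After smoothing away segments shorter than 3 Mb, a transition is a
    breakpoint between two adjacent segments, each of at least 10 Mb,
    whose genomic gap is at most 3 Mb."""
    n = 0
    for arm in _arm_segments(profile):
        smoothed = _smooth_arm(arm, params)
        for a, b in zip(smoothed, smoothed[1:]):
            len_a = a[1] - a[0] + 1
            len_b = b[1] - b[0] + 1
            gap = b[0] - a[1] - 1
            if (
                len_a >= params.lst_min_segment
                and len_b >= params.lst_min_segment
                and gap <= params.lst_max_gap
                and a[2:] != b[2:]
            ):
                n += 1
    return n


def hrd_score(profile: SegmentProfile, params: ScarParams = DEFAULT_SCAR_PARAMS) -> HrdScore:
    """LOH + ntAI + LST counts of one profile."""
    return HrdScore(
        loh_count=count_loh(profile, params),
        tai_count=count_tai(profile, params),
        lst_count=count_lst(profile, params),
    )


def deleterious_brca_mutations(
    mutations: pd.DataFrame,
    genes: tuple[str, ...] = ("BRCA1", "BRCA2"),
    consequences: frozenset[str] = DELETERIOUS_CONSEQUENCES,
) -> pd.DataFrame:
    """Filter a mutation table to deleterious BRCA1/2 calls."""
    if mutations.empty:
        return mutations
    mask = mutations["gene"].isin(genes) & mutations["consequence"].isin(consequences)
    return mutations[mask]


def classify_hr_status(
    score: HrdScore,
    brca_mutations: pd.DataFrame | None = None,
    threshold: int = 42,
    sample_id: str = "",
) -> HrStatusCall:
    """HR-deficient iff a deleterious tumour BRCA1/2 mutation is present or
    the scar score total meets the threshold (inclusive)."""
    tbrca = brca_mutations is not None and len(brca_mutations) > 0
    deficient = tbrca or score.total >= threshold
    return HrStatusCall(
        sample_id=sample_id,
        tbrca_mutated=tbrca,
        hrd_score=score,
        threshold=threshold,
        status=HR_DEFICIENT if deficient else HR_PROFICIENT,
    )


def call_brca1_methylation(
    betas: pd.Series,
    sample_id: str = "",
    probe: str = "cg13782816",
    cutoff: float = 0.9,
) -> MethylationCall:
    """Epigenetic-silencing call: beta strictly above the cutoff.

    ``betas`` is one sample's probe -> beta series.  A missing probe (or a
    missing value) yields an explicit missing-data call, never False.
    """
    if probe not in betas.index or pd.isna(betas[probe]):
        return MethylationCall(sample_id, probe, None, None, missing=True)
    beta = float(betas[probe])
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value {beta} for probe {probe} outside [0, 1]")
    return MethylationCall(sample_id, probe, beta, beta > cutoff, missing=False)


def locate_promoter_probes(
    probe_positions: pd.DataFrame,
    tss_table: pd.DataFrame,
    upstream: int = 1500,
    downstream: int = 500,
) -> pd.DataFrame:
    """Assign probes to gene promoters.

    The promoter is the closed interval from ``upstream`` bp before to
    ``downstream`` bp after the TSS, in transcription orientation (flipped
    for minus-strand genes).  Genes with unknown strand are skipped with a
    warning.

    ``probe_positions``: probe, chrom, pos.  ``tss_table``: gene, chrom,
    tss, strand.  Returns a (probe, gene) table.
    """
    out = []
    for g in tss_table.itertuples():
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        elif g.strand == "-":
            lo, hi = g.tss - downstream, g.tss + upstream
        else:
            warnings.warn(f"gene {g.gene}: unknown strand {g.strand!r}, skipped")
            continue
        hits = probe_positions[
            (probe_positions["chrom"] == g.chrom)
            & (probe_positions["pos"] >= lo)
            & (probe_positions["pos"] <= hi)
        ]
        for p in hits.itertuples():
            out.append({"probe": p.probe, "gene": g.gene})
    return pd.DataFrame(out, columns=["probe", "gene"])


def compute_tmb(
    mutations: pd.DataFrame,
    nonsynonymous: frozenset[str] = NONSYNONYMOUS_CONSEQUENCES,
) -> int:
    """Tumour mutation burden: the number of distinct nonsynonymous SNVs and
    indels.  Identical variant rows (same sample, chrom, pos, ref, alt) are
    counted once."""
    if mutations.empty:
        return 0
    nonsyn = mutations[mutations["consequence"].isin(nonsynonymous)]
    key_cols = [c for c in ("sample", "chrom", "pos", "ref", "alt") if c in nonsyn.columns]
    return int(len(nonsyn.drop_duplicates(subset=key_cols)))


def score_cohort(
    segments: pd.DataFrame,
    genome: GenomeAnnotation,
    mutations: pd.DataFrame | None = None,
    threshold: int = 42,
    params: ScarParams = DEFAULT_SCAR_PARAMS,
) -> pd.DataFrame:
    """Scar scores and HR status for every sample in a long-format segment
    table (columns: sample + segment columns)."""
    muts = mutations if mutations is not None else pd.DataFrame(
        columns=["sample", "gene", "consequence"]
    )
    rows = []
    for sample, sub in segments.groupby("sample", sort=True):
        profile = SegmentProfile(sample, sub[SEGMENT_COLUMNS], genome)
        score = hrd_score(profile, params)
        brca = deleterious_brca_mutations(muts[muts["sample"] == sample]) if len(muts) else None
        call = classify_hr_status(score, brca, threshold=threshold, sample_id=sample)
        rows.append(
            {
                "sample": sample,
                "loh": score.loh_count,
                "tai": score.tai_count,
                "lst": score.lst_count,
                "hrd_score": score.total,
                "tbrca_mutated": call.tbrca_mutated,
                "hr_status": call.status,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
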