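"""Literal-definition brute-force scar counters, kept independent of the
package implementation: plain loops over dict records, used only as the
oracle in equivalence tests."""

from __future__ import annotations

LOH_MIN = 15_000_000
TAI_MIN = 11_000_000
LST_MIN_SEG = 10_000_000
LST_SMOOTH = 3_000_000
LST_GAP = 3_000_000


def _records(profile):
    out = []
    for row in profile.segments.itertuples():
        out.append(
            {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "total": int(row.total_cn),
                "minor": int(row.minor_cn),
            }
        )
    return out


def oracle_loh(profile):
    n = 0
    for r in _records(profile):
        ann = profile.genome[r["chrom"]]
        length = r["end"] - r["start"] + 1
        if (
            r["minor"] == 0
            and r["total"] >= 1
            and length > LOH_MIN
            and not (r["start"] <= 1 and r["end"] >= ann.length)
        ):
            n += 1
    return n


def oracle_tai(profile):
    n = 0
    for r in _records(profile):
        ann = profile.genome[r["chrom"]]
        length = r["end"] - r["start"] + 1
        imbalanced = r["minor"] != r["total"] - r["minor"]
        telomeric = r["start"] <= 1 or r["end"] >= ann.length
        crosses = r["start"] < ann.cen_start and r["end"] > ann.cen_end
        if imbalanced and telomeric and not crosses and length > TAI_MIN:
            n += 1
    return n


def _oracle_smooth(arm):
    segs = [dict(s) for s in arm]
    while True:
        lengths = [s["end"] - s["start"] + 1 for s in segs]
        small = [(ln, i) for i, ln in enumerate(lengths) if ln < LST_SMOOTH]
        if not small:
            break
        _, i = min(small)
        if len(segs) == 1:
            return []
        neighbours = []
        if i > 0:
            neighbours.append((lengths[i - 1], 1, i - 1))  # prefer left on ties
        if i < len(segs) - 1:
            neighbours.append((lengths[i + 1], 0, i + 1))
        _, _, j = max(neighbours)
        segs[j]["start"] = min(segs[j]["start"], segs[i]["start"])
        segs[j]["end"] = max(segs[j]["end"], segs[i]["end"])
        del segs[i]
    out = []
    for s in segs:
        if (
            out
            and out[-1]["total"] == s["total"]
            and out[-1]["minor"] == s["minor"]
            and s["start"] == out[-1]["end"] + 1
        ):
            out[-1]["end"] = s["end"]
        else:
            out.append(dict(s))
    return out


def oracle_lst(profile):
    per_arm = {}
    for r in _records(profile):
        ann = profile.genome[r["chrom"]]
        if r["start"] < ann.cen_start:
            part = dict(r)
            part["end"] = min(r["end"], ann.cen_start - 1)
            per_arm.setdefault((r["chrom"], "p"), []).append(part)
        if r["end"] > ann.cen_end:
            part = dict(r)
            part["start"] = max(r["start"], ann.cen_end + 1)
            per_arm.setdefault((r["chrom"], "q"), []).append(part)
    n = 0
    for arm in per_arm.values():
        arm = sorted(arm, key=lambda s: s["start"])
        smoothed = _oracle_smooth(arm)
        for a, b in zip(smoothed, smoothed[1:]):
            if (
                a["end"] - a["start"] + 1 >= LST_MIN_SEG
                and b["end"] - b["start"] + 1 >= LST_MIN_SEG
                and b["start"] - a["end"] - 1 <= LST_GAP
                and (a["total"], a["minor"]) != (b["total"], b["minor"])
            ):
                n += 1
    return n
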