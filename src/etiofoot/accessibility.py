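"""Open-chromatin peak calling, DHS set algebra, and accessibility profiles.

The peak caller is a deliberately simple windowed fold-over-global-rate
scanner: the bespoke content of this module is everything downstream of peak
calling (time-course set algebra, TSS-centred profiles, feature annotation),
and externally produced narrowPeak intervals are accepted interchangeably.
"""

from __future__ import annotations

import numpy as np

from .core import (CutProfile, DHSCollection, GeneAnnotation,
                   intersect_intervals, merge_intervals, subtract_intervals)

TIME_POINTS = (0.0, 0.5, 2.0, 4.0, 24.0)


def call_peaks(profile: CutProfile, window: int = 100, fold_threshold: float = 4.0,
               merge_gap: int = 100, min_width: int = 100,
               label: str | None = None) -> DHSCollection:
    """Maximal runs where the windowed pooled cut rate exceeds
    fold_threshold x the global rate, merged within merge_gap and filtered by
    min_width. An all-zero profile yields an empty collection."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if not profile.counts:
        raise ValueError("empty profile")
    label = label if label is not None else profile.label
    intervals = {}
    total = profile.library_size
    length = sum(len(profile.counts[c]["+"]) for c in profile.counts)
    if total == 0:
        return DHSCollection(label, {})
    global_rate = total / length
    kernel = np.ones(window) / window
    for chrom in profile.chroms():
        pooled = profile.pooled(chrom).astype(float)
        smoothed = np.convolve(pooled, kernel, mode="same")
        above = smoothed >= fold_threshold * global_rate
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = np.nonzero(edges == 1)[0] + 1
        ends = np.nonzero(edges == -1)[0] + 1
        if above[0]:
            starts = np.concatenate([[0], starts])
        if above[-1]:
            ends = np.concatenate([ends, [len(above)]])
        runs = merge_intervals(np.stack([starts, ends], axis=1), gap=merge_gap)
        runs = runs[(runs[:, 1] - runs[:, 0]) >= min_width]
        if len(runs):
            intervals[chrom] = runs
    return DHSCollection(label, intervals)


def classify_dhs_sets(collections: dict[float, DHSCollection]
                      ) -> tuple[DHSCollection, DHSCollection]:
    """Split a five-time-point DHS course into hyperconserved and
    light-specific position sets.

    Hyperconserved positions are covered at all five time points;
    light-specific positions are covered at all four light time points but
    not in the dark (0 h). The two outputs are disjoint by construction.
    """
    missing = [t for t in TIME_POINTS if t not in collections]
    if missing:
        raise ValueError(f"missing time points: {missing}")
    dark = collections[0.0]
    light = [collections[t] for t in TIME_POINTS[1:]]
    chroms = sorted(set().union(*[set(c.intervals) for c in collections.values()]))
    hyper, light_only = {}, {}
    for chrom in chroms:
        common_light = light[0].get(chrom)
        for c in light[1:]:
            common_light = intersect_intervals(common_light, c.get(chrom))
        d = dark.get(chrom)
        h = intersect_intervals(common_light, d)
        ls = subtract_intervals(common_light, d)
        if len(h):
            hyper[chrom] = h
        if len(ls):
            light_only[chrom] = ls
    return (DHSCollection("hyperconserved", hyper),
            DHSCollection("light_specific", light_only))


def spot_score(profile: CutProfile, peaks: DHSCollection) -> float:
    """Fraction of all cuts (both strands) inside peak intervals."""
    total = profile.library_size
    if total == 0:
        raise ValueError("SPOT score undefined for a profile with zero cuts")
    inside = 0
    for chrom in peaks.chroms():
        if chrom not in profile.counts:
            continue
        pooled = profile.pooled(chrom)
        for s, e in peaks.get(chrom):
            inside += int(pooled[s:e].sum())
    return inside / total


def tss_profile(profile_a: CutProfile, annotation: GeneAnnotation,
                mode: str = "depth", profile_b: CutProfile | None = None,
                flank: int = 2000, eps: float = 0.5) -> dict:
    """Mean accessibility around TSSs, offsets -flank..+flank.

    depth mode: per-offset mean of depth-normalized (cuts-per-million) pooled
    counts across genes, with minus-strand genes reflected so upstream is
    always at negative offsets. logratio mode: per-offset mean of
    log2((a+eps)/(b+eps)) of the normalized counts of the two profiles.
    """
    if mode not in ("depth", "logratio"):
        raise ValueError(mode)
    if mode == "logratio" and profile_b is None:
        raise ValueError("logratio mode requires profile_b")
    norm_a = {c: profile_a.normalized(c) for c in profile_a.chroms()}
    norm_b = ({c: profile_b.normalized(c) for c in profile_b.chroms()}
              if profile_b is not None else None)
    width = 2 * flank + 1
    acc = np.zeros(width)
    n_genes = 0
    for g in annotation:
        arr_a = norm_a.get(g.chrom)
        if arr_a is None:
            continue
        tss = g.tss
        if tss - flank < 0 or tss + flank + 1 > len(arr_a):
            continue
        sl = slice(tss - flank, tss + flank + 1)
        a = arr_a[sl]
        if mode == "depth":
            vals = a
        else:
            b = norm_b[g.chrom][sl]
            vals = np.log2((a + eps) / (b + eps))
        if g.strand == "-":
            vals = vals[::-1]
        acc += vals
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no genes eligible for the TSS profile")
    return {"offsets": np.arange(-flank, flank + 1), "values": acc / n_genes,
            "n_genes": n_genes, "mode": mode}


def nearest_tss_distances(intervals: DHSCollection,
                          annotation: GeneAnnotation) -> list[int]:
    """Signed midpoint-to-nearest-TSS distances, negative upstream.

    Distance is measured along the nearest gene's orientation: negative
    values lie 5' (upstream) of that TSS, positive values downstream. Ties in
    absolute distance break toward the lower-coordinate TSS.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    by_chrom: dict[str, list] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand))
    for v in by_chrom.values():
        v.sort()
    out = []
    for chrom, s, e in intervals.to_records():
        cands = by_chrom.get(chrom)
        if not cands:
            continue
        mid = (s + e - 1) // 2
        tss, strand = min(cands, key=lambda c: (abs(mid - c[0]), c[0]))
        d = mid - tss if strand == "+" else tss - mid
        out.append(int(d))
    return out


FEATURE_PRECEDENCE = ("promoter", "five_utr", "cds", "intron", "three_utr")


def annotate_features(intervals: DHSCollection, annotation: GeneAnnotation,
                      chrom_lengths: dict[str, int],
                      precedence=FEATURE_PRECEDENCE) -> dict[str, int]:
    """Assign each interval one feature category by its midpoint.

    Precedence (default promoter > 5'UTR > CDS > intron > 3'UTR) resolves
    overlaps; anything else is intergenic. Counts sum to the interval count.
    """
    feature_arrays = _feature_intervals(annotation, chrom_lengths)
    counts = {f: 0 for f in (*precedence, "intergenic")}
    for chrom, s, e in intervals.to_records():
        mid = (s + e - 1) // 2
        cat = "intergenic"
        for f in precedence:
            arr = feature_arrays[f].get(chrom)
            if arr is not None and _covers(arr, mid):
                cat = f
                break
        counts[cat] += 1
    return counts


def _covers(merged: np.ndarray, pos: int) -> bool:
    i = np.searchsorted(merged[:, 0], pos, side="right") - 1
    return i >= 0 and pos < merged[i, 1]


def _feature_intervals(annotation: GeneAnnotation,
                       chrom_lengths: dict[str, int]) -> dict[str, dict[str, np.ndarray]]:
    raw: dict[str, dict[str, list]] = {f: {} for f in FEATURE_PRECEDENCE}
    for g in annotation:
        limit = chrom_lengths.get(g.chrom)
        p = g.promoter(annotation.promoter_length, chrom_length=limit)
        raw["promoter"].setdefault(g.chrom, []).append((p.start, p.end))
        for field, name in (("five_utr", "five_utr"), ("cds", "cds"),
                            ("introns", "intron"), ("three_utr", "three_utr")):
            for s, e in getattr(g, field):
                raw[name].setdefault(g.chrom, []).append((s, e))
    return {
        f: {c: merge_intervals(np.array(v)) for c, v in per.items()}
        for f, per in raw.items()
    }


def feature_density(feature_counts: dict[str, int], annotation: GeneAnnotation,
                    chrom_lengths: dict[str, int]) -> dict[str, float | None]:
    """Counts per base of each feature class; zero-length features yield None."""
    arrays = _feature_intervals(annotation, chrom_lengths)
    lengths = {
        f: sum(int(np.sum(a[:, 1] - a[:, 0])) for a in per.values())
        for f, per in arrays.items()
    }
    genome_total = sum(chrom_lengths.values())
    covered = _union_all(arrays, chrom_lengths)
    lengths["intergenic"] = genome_total - covered
    out = {}
    for f, count in feature_counts.items():
        total = lengths.get(f, 0)
        out[f] = count / total if total > 0 else None
    return out


def _union_all(arrays, chrom_lengths) -> int:
    per_chrom: dict[str, list] = {}
    for per in arrays.values():
        for c, a in per.items():
            per_chrom.setdefault(c, []).append(a)
    total = 0
    for c, parts in per_chrom.items():
        merged = merge_intervals(np.concatenate(parts))
        total += int(np.sum(merged[:, 1] - merged[:, 0]))
    return total


def locus_fold_change(profile_late: CutProfile, profile_dark: CutProfile,
                      loci: list[tuple[str, int, int]], eps: float = 0.1) -> list[dict]:
    """Per-locus ratio of mean normalized depth, late (24 h) over dark.

    eps is added to both means; loci whose dark mean is below eps are flagged
    as eps-dominated.
    """
    if not loci:
        raise ValueError("empty locus list")
    norm_late = {c: profile_late.normalized(c) for c in profile_late.chroms()}
    norm_dark = {c: profile_dark.normalized(c) for c in profile_dark.chroms()}
    out = []
    for chrom, s, e in loci:
        m_late = float(norm_late[chrom][s:e].mean())
        m_dark = float(norm_dark[chrom][s:e].mean())
        out.append({
            "chrom": chrom, "start": s, "end": e,
            "fold_change": (m_late + eps) / (m_dark + eps),
            "eps_dominated": m_dark < eps,
        })
    return out
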