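"""Position weight matrices, exact-p-value scanning, and motif censuses.

Scores are log2 likelihood ratios against a background base distribution,
discretized onto a fixed grid (default 1e-3 bits per bin). P-values are exact
for the discretized score function: the full distribution of window scores
under the background model is built by dynamic programming (one shift-add
convolution per PWM column), so a hit's p-value is the exact probability that
a random background sequence of the same width scores at least as high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BASE_INDEX, GenomeSequence, revcomp

SCORE_BIN = 1e-3  # bits
_SCORE_FLOOR = -20.0  # bits per position; stands in for log2(0)


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        codes[raw == ord(b)] = i
    return codes


class PWM:
    """A probability matrix with discretized log-odds scores and exact p-values."""

    def __init__(self, motif_id: str, probs: np.ndarray,
                 background: np.ndarray | None = None,
                 group: str | None = None, score_bin: float = SCORE_BIN):
        probs = np.asarray(probs, dtype=float)
        if probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probability matrix must be 4 x width")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("probability columns must sum to 1")
        self.motif_id = motif_id
        self.probs = probs
        self.background = (np.full(4, 0.25) if background is None
                           else np.asarray(background, dtype=float))
        if np.any(self.background <= 0) or abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must be a positive distribution")
        self.group = group
        self.score_bin = score_bin
        with np.errstate(divide="ignore"):
            raw = np.log2(probs / self.background[:, None])
        raw = np.maximum(raw, _SCORE_FLOOR)
        # the integer-bin matrix IS the score function; floats derive from it
        self.score_ints = np.round(raw / score_bin).astype(np.int64)
        self._tail = None

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def scores(self) -> np.ndarray:
        """Discretized log2-odds score matrix (bits)."""
        return self.score_ints * self.score_bin

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, strength: float = 0.9,
                       **kw) -> "PWM":
        w = len(consensus)
        probs = np.full((4, w), (1 - strength) / 3)
        for i, b in enumerate(consensus):
            probs[BASE_INDEX[b], i] = strength
        return cls(motif_id, probs, **kw)

    def score_window(self, seq: str) -> float:
        codes = _encode(seq)
        if len(codes) != self.width or np.any(codes < 0):
            raise ValueError("window must be N-free and of motif width")
        return float(self.score_ints[codes, np.arange(self.width)].sum()
                     * self.score_bin)

    # ---------------------------------------------------------- exact p-values

    def _tail_table(self):
        """(offset, sf) with sf[k] = P(shifted integer score >= k)."""
        if self._tail is not None:
            return self._tail
        mins = self.score_ints.min(axis=0)
        shifted = self.score_ints - mins  # non-negative per column
        size = int(shifted.max(axis=0).sum()) + 1
        pmf = np.zeros(size)
        pmf[0] = 1.0
        top = 0
        for j in range(self.width):
            new = np.zeros(size)
            for b in range(4):
                s = int(shifted[b, j])
                new[s:top + s + 1] += pmf[:top + 1] * self.background[b]
            pmf = new
            top += int(shifted[:, j].max())
        sf = np.cumsum(pmf[::-1])[::-1]
        self._tail = (int(mins.sum()), sf)
        return self._tail

    def pvalue_of_int(self, total_int) -> np.ndarray:
        """Exact p-value(s) for integer-bin total score(s)."""
        offset, sf = self._tail_table()
        k = np.asarray(total_int, dtype=np.int64) - offset
        k = np.clip(k, 0, len(sf))  # above max score -> p of empty set = 0
        padded = np.append(sf, 0.0)
        return padded[k]

    def pvalue(self, score_bits: float) -> float:
        return float(self.pvalue_of_int(np.round(score_bits / self.score_bin)))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float  # bits
    p_value: float
    group: str | None = None


@dataclass
class MotifGroupMap:
    motif_to_group: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m, g in self.motif_to_group.items():
            out.setdefault(g, []).append(m)
        return out

    def group_of(self, motif_id: str) -> str:
        return self.motif_to_group.get(motif_id, "ungrouped")


def pwm_from_counts(motif_id: str, counts: np.ndarray, pseudocount: float = 1.0,
                    background: np.ndarray | None = None, **kw) -> PWM:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError("all-zero column with zero pseudocount")
    probs = (counts + pseudocount) / (colsums + 4 * pseudocount)
    return PWM(motif_id, probs, background=background, **kw)


# ------------------------------------------------------------------ scanning

def _scan_codes(pwm: PWM, codes: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores at every N-free start position."""
    n = len(codes) - pwm.width + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for j in range(pwm.width):
        window = safe[j:j + n]
        total += ints[window, j]
        valid &= codes[j:j + n] >= 0
    return total, valid


def scan_sequence(pwm: PWM, sequence: str, p_threshold: float = 1e-4,
                  both_strands: bool = True, chrom: str = "seq",
                  offset: int = 0) -> list[MotifHit]:
    """All motif occurrences with exact p-value <= threshold.

    Reverse-strand hits score the reverse complement of the window with the
    forward matrix; both strands share one null distribution.
    """
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    strands = [("+", pwm.score_ints)]
    if both_strands:
        rc_ints = pwm.score_ints[::-1, ::-1]  # complement bases, reverse columns
        strands.append(("-", rc_ints))
    for strand, ints in strands:
        total, valid = _scan_codes(pwm, codes, ints)
        if not len(total):
            continue
        pvals = pwm.pvalue_of_int(total)
        keep = valid & (pvals <= p_threshold)
        for i in np.nonzero(keep)[0]:
            hits.append(MotifHit(
                pwm.motif_id, chrom, offset + int(i), offset + int(i) + pwm.width,
                strand, float(total[i] * pwm.score_bin), float(pvals[i]),
                group=pwm.group,
            ))
    return hits


def scan_intervals(pwms: list[PWM], genome: GenomeSequence, intervals,
                   p_threshold: float = 1e-4, both_strands: bool = True) -> list[MotifHit]:
    """Scan every (chrom, start, end) interval with every PWM."""
    hits = []
    for chrom, start, end in intervals:
        seq = genome.fetch(chrom, start, end)
        for pwm in pwms:
            hits.extend(scan_sequence(pwm, seq, p_threshold, both_strands,
                                      chrom=chrom, offset=start))
    return hits


def assign_groups(hits: list[MotifHit], group_map: MotifGroupMap) -> tuple[list[MotifHit], int]:
    """Label every hit with its motif group; returns (hits, n_ungrouped)."""
    out = []
    ungrouped = 0
    for h in hits:
        g = group_map.group_of(h.motif_id)
        if g == "ungrouped":
            ungrouped += 1
        out.append(MotifHit(h.motif_id, h.chrom, h.start, h.end, h.strand,
                            h.score, h.p_value, group=g))
    return out, ungrouped


def count_nonoverlapping(hits: list[MotifHit], region: tuple[str, int, int] | None = None,
                         scope: str = "per-group") -> dict[str, int]:
    """Greedy non-overlapping occurrence counts per motif or per group.

    Hits are taken in ascending p-value order (ties: leftmost start, then
    motif id); a hit is kept only if it overlaps no previously kept hit in the
    same scope unit.
    """
    if scope not in ("per-motif", "per-group"):
        raise ValueError(scope)
    key = (lambda h: h.motif_id) if scope == "per-motif" else (lambda h: h.group)
    pool = hits
    if region is not None:
        chrom, s, e = region
        pool = [h for h in hits if h.chrom == chrom and h.start >= s and h.end <= e]
    ordered = sorted(pool, key=lambda h: (h.p_value, h.start, h.motif_id))
    kept: dict[str, list[tuple[int, str]]] = {}
    counts: dict[str, int] = {}
    for h in ordered:
        unit = key(h)
        clash = any(h.start < e and s < h.end and c == h.chrom
                    for s, e, c in kept.get(unit, []))
        if not clash:
            kept.setdefault(unit, []).append((h.start, h.end, h.chrom))
            counts[unit] = counts.get(unit, 0) + 1
    return counts


def count_lres(gene, hits: list[MotifHit], family_map: MotifGroupMap,
               upstream: int = 1500, chrom_length: int | None = None) -> dict[str, int]:
    """Non-overlapping LRE-family counts from 1.5 kb upstream to the CDS end."""
    if not gene.cds:
        raise ValueError(f"gene {gene.gene_id} lacks a CDS")
    if gene.strand == "+":
        s, e = gene.tss - upstream, gene.cds_end
    else:
        s, e = gene.cds_end, gene.tss + 1 + upstream
    s = max(0, s)
    if chrom_length is not None:
        e = min(e, chrom_length)
    grouped, _ = assign_groups([h for h in hits if h.chrom == gene.chrom],
                               family_map)
    return count_nonoverlapping(grouped, region=(gene.chrom, s, e),
                                scope="per-group")


def cluster_pwms(pwms: list[PWM], similarity_threshold: float = 0.8) -> MotifGroupMap:
    """Single-linkage grouping on best-offset Pearson column correlation."""
    if len(pwms) < 2:
        raise ValueError("clustering needs >= 2 motifs")

    def best_corr(a: PWM, b: PWM) -> float:
        best = -1.0
        for bm in (b.probs, b.probs[::-1, ::-1]):
            wa, wb = a.probs.shape[1], bm.shape[1]
            for off in range(-(wb - 1), wa):
                lo, hi = max(0, off), min(wa, off + wb)
                if hi - lo < 4:
                    continue
                x = a.probs[:, lo:hi].ravel()
                y = bm[:, lo - off:hi - off].ravel()
                if x.std() == 0 or y.std() == 0:
                    continue
                best = max(best, float(np.corrcoef(x, y)[0, 1]))
        return best

    ids = [p.motif_id for p in pwms]
    parent = list(range(len(pwms)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pwms)):
        for j in range(i + 1, len(pwms)):
            if best_corr(pwms[i], pwms[j]) >= similarity_threshold:
                parent[find(i)] = find(j)
    roots = sorted(set(find(i) for i in range(len(pwms))))
    label = {r: f"cluster_{k}" for k, r in enumerate(roots)}
    return MotifGroupMap({ids[i]: label[find(i)] for i in range(len(pwms))})
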