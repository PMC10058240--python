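"""Core genomic containers and interval algebra.

All coordinates are 0-based half-open throughout the package; BED-style
intervals are emitted natively and GFF3 is converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Per-chromosome sequences over {A,C,G,T,N}."""

    def __init__(self, chroms: dict[str, str]):
        for name, seq in chroms.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name} contains non-ACGTN symbols: {bad}")
        self.chroms = dict(chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]

    def encode(self, chrom: str) -> np.ndarray:
        """Base codes A=0 C=1 G=2 T=3, N=-1 (int8)."""
        raw = np.frombuffer(self.chroms[chrom].encode("ascii"), dtype=np.uint8)
        codes = np.full(raw.shape, -1, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            codes[raw == ord(b)] = i
        return codes


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # ties at exact midpoints break toward the lower coordinate
        return (self.start + self.end - 1) // 2


@dataclass
class GeneModel:
    """Single-isoform gene model; feature intervals are 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    five_utr: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)
    three_utr: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """TSS position (the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds_end(self) -> int:
        """Stop-codon-side CDS boundary in genomic coordinates.

        For + genes this is the half-open end of the last CDS segment; for -
        genes the (inclusive-start) genomic coordinate of the first segment.
        """
        if not self.cds:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        if self.strand == "+":
            return max(e for _, e in self.cds)
        return min(s for s, _ in self.cds)

    def promoter(self, length: int = 2000, chrom_length: int | None = None) -> GenomicInterval:
        if self.strand == "+":
            s, e = self.start - length, self.start
        else:
            s, e = self.end, self.end + length
        s = max(0, s)
        if chrom_length is not None:
            e = min(chrom_length, e)
        e = max(e, s + 1)
        return GenomicInterval(self.chrom, s, e, self.strand)


class GeneAnnotation:
    def __init__(self, genes: list[GeneModel], promoter_length: int = 2000):
        self.genes = list(genes)
        self.promoter_length = promoter_length
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]


# ---------------------------------------------------------------------------
# interval algebra on (n, 2) integer arrays, sorted and merged
# ---------------------------------------------------------------------------

def merge_intervals(arr: np.ndarray, gap: int = 0) -> np.ndarray:
    """Sort and merge intervals closer than `gap` (gap=0 merges abutting)."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(arr, dtype=np.int64)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged, sorted interval arrays."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b, both merged and sorted."""
    out = []
    j = 0
    b = np.asarray(b, dtype=np.int64)
    for s, e in np.asarray(a, dtype=np.int64):
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def interval_coverage(arr: np.ndarray) -> int:
    if len(arr) == 0:
        return 0
    return int(np.sum(arr[:, 1] - arr[:, 0]))


class DHSCollection:
    """Labelled open-chromatin intervals, sorted and merged per chromosome."""

    def __init__(self, label: str, intervals: dict[str, np.ndarray]):
        self.label = label
        self.intervals = {c: merge_intervals(v) for c, v in intervals.items() if len(v)}

    @classmethod
    def from_records(cls, label: str, records) -> "DHSCollection":
        by_chrom: dict[str, list] = {}
        for chrom, s, e in records:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(label, {c: np.array(v) for c, v in by_chrom.items()})

    def chroms(self):
        return sorted(self.intervals)

    def get(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self):
        return sum(len(v) for v in self.intervals.values())

    def total_coverage(self) -> int:
        return sum(interval_coverage(v) for v in self.intervals.values())

    def to_records(self):
        for c in self.chroms():
            for s, e in self.intervals[c]:
                yield c, int(s), int(e)


@dataclass
class CutProfile:
    """Per-base strand-specific 5' DNase cut counts for one sample."""

    label: str
    counts: dict[str, dict[str, np.ndarray]]  # chrom -> {"+": arr, "-": arr}
    time_point: float | None = None
    replicate: int | None = None
    species: str | None = None
    treatment: str = "nuclei"  # or "deproteinated"

    def __post_init__(self):
        for chrom, strands in self.counts.items():
            for strand, arr in strands.items():
                if np.any(arr < 0):
                    raise ValueError(f"negative counts on {chrom}{strand}")

    @property
    def library_size(self) -> int:
        return int(
            sum(int(a.sum()) for s in self.counts.values() for a in s.values())
        )

    def chroms(self):
        return sorted(self.counts)

    def pooled(self, chrom: str) -> np.ndarray:
        s = self.counts[chrom]
        return s["+"] + s["-"]

    def normalized(self, chrom: str) -> np.ndarray:
        """Pooled counts scaled to cuts per million (per base)."""
        total = self.library_size
        if total == 0:
            raise ValueError("empty profile cannot be depth-normalized")
        return self.pooled(chrom) * (1e6 / total)
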