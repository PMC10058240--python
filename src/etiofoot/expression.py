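"""Expression normalization, DE calling, and cross-species induction comparison.

The normalization chain mirrors a common cross-species workflow: per-sample
quantile normalization, then division by the sample mean so that a value of 1
is the average transcript at that time point. DE calling deliberately uses two
independent tests and reports only their intersection as "robust" calls.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneAnnotation


@dataclass
class ExpressionMatrix:
    """Genes x samples values plus per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns are sample names.
    ``metadata``: DataFrame indexed by sample name with columns
    species / time_point / replicate.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def time_points(self) -> list[float]:
        return sorted(self.metadata["time_point"].unique())

    def samples_at(self, time_point: float) -> list[str]:
        md = self.metadata
        return list(md.index[md["time_point"] == time_point])

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.metadata.copy())


@dataclass
class OrthologMap:
    """Orthogroup id -> {species: [gene ids]}."""

    groups: dict[str, dict[str, list[str]]]

    def validate(self, matrices: dict[str, ExpressionMatrix]) -> list[str]:
        """Return orthogroups whose members are missing from their matrix."""
        flagged = []
        for og, members in self.groups.items():
            for species, genes in members.items():
                if species not in matrices:
                    raise ValueError(f"unknown species {species} in {og}")
                idx = matrices[species].values.index
                if any(g not in idx for g in genes):
                    flagged.append(og)
                    break
        return flagged


@dataclass
class DEResult:
    gene_id: str
    called_a: bool
    called_b: bool
    log2_fold: float

    @property
    def robust(self) -> bool:
        return self.called_a and self.called_b


# ------------------------------------------------------------ annotation fix

def extend_pseudo_utr(annotation: GeneAnnotation, length: int = 339,
                      chrom_lengths: dict[str, int] | None = None) -> GeneAnnotation:
    """Give UTR-less genes a fixed-length pseudo-3'UTR past the stop codon.

    Genes that already have a 3'UTR are untouched. The extension is clipped
    at chromosome ends (clips are recorded on the returned annotation as
    ``.clipped`` gene ids).
    """
    if length <= 0:
        raise ValueError("extension length must be positive")
    out = copy.deepcopy(annotation)
    clipped = []
    for g in out.genes:
        if g.three_utr or not g.cds:
            continue
        limit = chrom_lengths.get(g.chrom) if chrom_lengths else None
        if g.strand == "+":
            s = g.cds_end
            e = s + length
            if limit is not None and e > limit:
                e = limit
                clipped.append(g.gene_id)
            if e > s:
                g.three_utr = [(s, e)]
                g.end = max(g.end, e)
        else:
            e = g.cds_end
            s = e - length
            if s < 0:
                s = 0
                clipped.append(g.gene_id)
            if e > s:
                g.three_utr = [(s, e)]
                g.start = min(g.start, s)
    out.clipped = clipped
    return out


# ------------------------------------------------------------ transforms

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic distribution.

    Ties within a column receive the mean of the order-statistic means they
    span (pandas "average" ranking).
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    sorted_mean = np.sort(df.values, axis=0).mean(axis=1)
    ranks = df.rank(method="average").values  # 1-based, possibly fractional
    lo = np.floor(ranks).astype(int) - 1
    hi = np.ceil(ranks).astype(int) - 1
    frac = ranks - np.floor(ranks)
    out = sorted_mean[lo] * (1 - frac) + sorted_mean[hi] * frac
    return matrix.copy_with(pd.DataFrame(out, index=df.index, columns=df.columns))


def sample_mean_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its mean so 1 marks the average transcript."""
    means = matrix.values.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"samples with non-positive mean: {bad}")
    return matrix.copy_with(matrix.values / means)


def row_mean_log_transform(values: pd.DataFrame, floor: float = 1e-9) -> pd.DataFrame:
    """log10(value / row mean), the heatmap transform; zeros floored."""
    means = values.mean(axis=1)
    if (means <= 0).any():
        raise ValueError("rows with non-positive mean cannot be log-transformed")
    ratio = values.div(means, axis=0).clip(lower=floor)
    return np.log10(ratio)


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores (sample sd); constant rows map to zero and are flagged."""
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 columns")
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    flagged = list(values.index[sds == 0])
    safe = sds.replace(0, 1.0)
    out = values.sub(means, axis=0).div(safe, axis=0)
    out.loc[flagged] = 0.0
    return out, flagged


# ------------------------------------------------------------ DE calling

def detect_de_genes(matrix: ExpressionMatrix, t_from: float, t_to: float,
                    alpha: float = 0.05, min_fold: float = 1.5,
                    min_mean_count: float = 5.0) -> list[DEResult]:
    """Two independent DE tests between consecutive time points, intersected.

    Method A: exact conditional Poisson test on replicate-summed counts (the
    sum at one condition is binomial given the total, p = n1/(n1+n2)).
    Method B: Welch t-test on log2(count+1) with a fold-change floor.
    Both are BH-corrected at ``alpha``; the robust set is the intersection.
    Genes below ``min_mean_count`` mean raw count are filtered before testing.
    """
    cols1 = matrix.samples_at(t_from)
    cols2 = matrix.samples_at(t_to)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("detect_de_genes requires >= 2 replicates per condition")
    x1 = matrix.values[cols1].values
    x2 = matrix.values[cols2].values
    keep = np.concatenate([x1, x2], axis=1).mean(axis=1) >= min_mean_count
    genes = matrix.values.index[keep]
    x1, x2 = x1[keep], x2[keep]
    if len(genes) == 0:
        return []

    n1, n2 = x1.shape[1], x2.shape[1]
    s1 = np.round(x1.sum(axis=1)).astype(np.int64)
    s2 = np.round(x2.sum(axis=1)).astype(np.int64)
    p_null = n1 / (n1 + n2)
    pa = np.array([
        stats.binomtest(int(a), int(a + b), p_null).pvalue if a + b > 0 else 1.0
        for a, b in zip(s1, s2)
    ])

    l1 = np.log2(x1 + 1.0)
    l2 = np.log2(x2 + 1.0)
    tt = stats.ttest_ind(l2, l1, axis=1, equal_var=False)
    pb = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)

    lfc = np.log2((x2.mean(axis=1) + 0.5) / (x1.mean(axis=1) + 0.5))

    qa = multipletests(pa, alpha=alpha, method="fdr_bh")[1]
    qb = multipletests(pb, alpha=alpha, method="fdr_bh")[1]
    called_a = qa < alpha
    called_b = (qb < alpha) & (np.abs(lfc) >= np.log2(min_fold))

    return [
        DEResult(g, bool(a), bool(b), float(f))
        for g, a, b, f in zip(genes, called_a, called_b, lfc)
    ]


# ------------------------------------------------------------ cross-species

def induction_comparison(matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix,
                         ortholog_map: OrthologMap, gene_set: list[str] | None = None,
                         pseudo: float = 0.01) -> pd.DataFrame:
    """Per-orthogroup induction (24 h vs 0 h) and species contrast.

    Both matrices must already be sample-mean scaled. Time points are aligned
    by nearest label. Returns a DataFrame with relative-abundance
    trajectories, per-species induction ratios, and the log2 contrast of
    species A's induction over species B's. Orthogroups with missing members
    are flagged and excluded from the contrast.
    """
    if gene_set is not None and len(gene_set) == 0:
        raise ValueError("empty gene set")
    tps_a = matrix_a.time_points
    tps_b = matrix_b.time_points
    aligned = [(t, min(tps_b, key=lambda u: abs(u - t))) for t in tps_a]

    def mean_traj(matrix, gene, tps):
        return np.array([
            matrix.values.loc[gene, matrix.samples_at(t)].mean() for t in tps
        ])

    rows = []
    for og, members in sorted(ortholog_map.groups.items()):
        genes_a = members.get("A", [])
        genes_b = members.get("B", [])
        if gene_set is not None and not any(g in gene_set for g in genes_a):
            continue
        ok_a = [g for g in genes_a if g in matrix_a.values.index]
        ok_b = [g for g in genes_b if g in matrix_b.values.index]
        flagged = len(ok_a) != len(genes_a) or len(ok_b) != len(genes_b) \
            or not ok_a or not ok_b
        if not ok_a or not ok_b:
            rows.append({"orthogroup": og, "flagged": True, "contrast_log2": np.nan,
                         "induction_a": np.nan, "induction_b": np.nan})
            continue
        traj_a = np.mean([mean_traj(matrix_a, g, [t for t, _ in aligned])
                          for g in ok_a], axis=0)
        traj_b = np.mean([mean_traj(matrix_b, g, [u for _, u in aligned])
                          for g in ok_b], axis=0)
        ind_a = (traj_a[-1] + pseudo) / (traj_a[0] + pseudo)
        ind_b = (traj_b[-1] + pseudo) / (traj_b[0] + pseudo)
        rows.append({
            "orthogroup": og,
            "flagged": flagged,
            "induction_a": float(ind_a),
            "induction_b": float(ind_b),
            "contrast_log2": float(np.log2(ind_a / ind_b)),
            "trajectory_a": traj_a.tolist(),
            "trajectory_b": traj_b.tolist(),
        })
    return pd.DataFrame(rows)
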