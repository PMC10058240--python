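"""Motif-group enrichment against open-chromatin backgrounds and
binding-trajectory statistics across the de-etiolation time course.

Enrichment compares a query set's motif-group composition against the
composition of hits in hyperconserved DHS restricted to expressed gene loci
(gene body plus 1.5-kb promoter): log2((obs + eps)/(exp + eps)) per group,
positive where a group is over-represented. Binding trajectories are
per-group hit proportions per time point (proportioning removes sequencing-
depth differences), mean-centred across the five time points; dark-vs-light
Pearson correlations across groups reproduce the binding-inversion readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifGroupMap, MotifHit


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # group, observed, obs_prop, exp_prop, log2_ratio
    gene_set_label: str
    background_label: str


def group_counts(hits: list[MotifHit]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for h in hits:
        g = h.group if h.group is not None else "ungrouped"
        counts[g] = counts.get(g, 0) + 1
    return counts


def background_frequencies(hits: list[MotifHit],
                           group_map: MotifGroupMap | None = None) -> dict[str, float]:
    """Expected per-group hit proportions from the background region set."""
    if group_map is not None:
        from .motifs import assign_groups
        hits, _ = assign_groups(hits, group_map)
    counts = group_counts(hits)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty background")
    return {g: c / total for g, c in counts.items()}


def enrichment_log_ratio(observed_hits: list[MotifHit],
                         background: dict[str, float],
                         pseudocount: float = 1.0,
                         gene_set_label: str = "query",
                         background_label: str = "background") -> EnrichmentResult:
    """Per-group log2 enrichment of a query hit set over the background."""
    counts = group_counts(observed_hits)
    unknown = set(counts) - set(background)
    if unknown:
        raise ValueError(f"groups absent from background universe: {sorted(unknown)}")
    total = sum(counts.values())
    eps = pseudocount / max(total, 1)
    rows = []
    for g in sorted(background):
        obs = counts.get(g, 0)
        obs_prop = obs / total if total else 0.0
        exp_prop = background[g]
        rows.append({
            "group": g, "observed": obs, "obs_prop": obs_prop,
            "exp_prop": exp_prop,
            "log2_ratio": float(np.log2((obs_prop + eps) / (exp_prop + eps))),
        })
    return EnrichmentResult(pd.DataFrame(rows), gene_set_label, background_label)


def dgf_motif_proportions(hits_by_time: dict[float, list[MotifHit]]
                          ) -> tuple[pd.DataFrame, list[float]]:
    """Per-group hit proportions per time point (depth-compensated).

    Time points with zero hits are excluded and returned as flagged.
    Rows are groups, columns are time points.
    """
    flagged = [t for t, hits in hits_by_time.items() if len(hits) == 0]
    usable = {t: hits for t, hits in hits_by_time.items() if hits}
    if not usable:
        raise ValueError("no time point has any hits")
    groups = sorted({g for hits in usable.values() for g in group_counts(hits)})
    data = {}
    for t in sorted(usable):
        counts = group_counts(usable[t])
        total = sum(counts.values())
        data[t] = [counts.get(g, 0) / total for g in groups]
    return pd.DataFrame(data, index=groups), flagged


def mean_center_trajectories(proportions: pd.DataFrame) -> pd.DataFrame:
    """Subtract each group's across-time mean; rows then sum to zero."""
    return proportions.sub(proportions.mean(axis=1), axis=0)


def dark_light_correlation(centered: pd.DataFrame, dark: float = 0.0,
                           method: str = "pearson") -> dict[float, float]:
    """Correlation of each light column against the dark column across groups.

    Zero-variance columns yield NaN (flagged by the caller via isnan).
    """
    if centered.shape[0] < 3:
        raise ValueError("correlation needs >= 3 motif groups")
    if dark not in centered.columns:
        raise ValueError("dark time point missing from trajectory matrix")
    dark_col = centered[dark].values
    out = {}
    for t in centered.columns:
        if t == dark:
            continue
        col = centered[t].values
        if np.std(dark_col) == 0 or np.std(col) == 0:
            out[t] = float("nan")
            continue
        if method == "pearson":
            out[t] = float(stats.pearsonr(dark_col, col).statistic)
        elif method == "spearman":
            out[t] = float(stats.spearmanr(dark_col, col).statistic)
        else:
            raise ValueError(method)
    return out
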