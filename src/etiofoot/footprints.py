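"""Digital genomic footprint detection and cutting-bias correction.

The footprint statistic is a strand-aware pair of one-sided binomial tests:
protein protection depletes 5' cut counts inside a candidate window relative
to its shoulders, with forward-strand cuts tested against the left shoulder
and reverse-strand cuts against the right. The per-candidate score is the sum
of the two log10 upper-tail probabilities; candidates scoring below a cutoff
(default -10) are kept greedily without overlap.

DNase I cuts with strong sequence preference, so an apparent "footprint" can
be a run of disfavoured hexamers. A deproteinated-DNA control estimates the
per-hexamer relative cutting rate; each footprint's bias-corrected depletion
statistic x = log((o_in/e_in)/(o_out/e_out)) is fed to a two-component
Gaussian mixture, and the footprint likelihood ratio (FLR) is the posterior
log-odds of the protected component. FLR < 0 marks depletion that the
sequence bias alone explains; those calls are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .core import BASE_INDEX, CutProfile, DHSCollection, GenomeSequence

_POWERS = 4 ** np.arange(5, -1, -1)
_LN10 = np.log(10.0)


def hexamer_indices(codes: np.ndarray, strand: str) -> tuple[np.ndarray, np.ndarray]:
    """Hexamer context index (0..4095) at every position; (-1 where invalid).

    A cut is assigned to the base immediately 3' of the nick on the strand of
    the read; the context is the 3 bases either side of that position, read
    in the strand's orientation (reverse-complemented for '-').
    """
    n = len(codes)
    cp = np.concatenate([np.full(3, -1, dtype=np.int64),
                         codes.astype(np.int64),
                         np.full(3, -1, dtype=np.int64)])
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for k in range(6):
        part = cp[k:k + n] if strand == "+" else cp[6 - k:6 - k + n]
        base = part if strand == "+" else 3 - part
        idx += np.where(part >= 0, base, 0) * _POWERS[k]
        valid &= part >= 0
    idx[~valid] = -1
    return idx, valid


def hexamer_to_index(hexamer: str) -> int:
    return int(sum(BASE_INDEX[b] * p for b, p in zip(hexamer, _POWERS)))


@dataclass
class HexamerBiasTable:
    """Relative cutting rate per hexamer, normalized to mean 1."""

    rates: np.ndarray  # length 4096
    pseudocount: float
    total_control_cuts: int
    absent: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.rates <= 0):
            raise ValueError("bias rates must be positive")

    def rate_of(self, hexamer: str) -> float:
        return float(self.rates[hexamer_to_index(hexamer)])


@dataclass
class Footprint:
    chrom: str
    start: int
    end: int
    time_point: float | None = None
    score: float = 0.0          # log10 combined binomial p
    x: float = np.nan           # bias-corrected depletion statistic
    flr: float = np.nan
    passed_filter: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class MixtureFit:
    weights: tuple[float, float]      # (footprint, background)
    means: tuple[float, float]
    scales: tuple[float, float]
    loglik_trace: list[float]
    converged: bool
    degenerate: bool = False


# ----------------------------------------------------------------- detection

def detect_footprints(profile: CutProfile, dhs: DHSCollection,
                      widths=range(11, 26, 2), shoulder: int = 35,
                      score_threshold: float = -10.0,
                      time_point: float | None = None) -> list[Footprint]:
    """Strand-aware binomial-shoulder footprint calls inside DHSs.

    Returns maximal non-overlapping candidates with score < threshold,
    greedily selected by ascending score (ties to the leftmost start).
    """
    widths = list(widths)
    if min(widths) < 6 or max(widths) > 40:
        raise ValueError("widths must lie in [6, 40]")
    if shoulder < 5:
        raise ValueError("shoulder must be >= 5")
    if score_threshold >= 0:
        raise ValueError("score threshold must be negative")
    tp = time_point if time_point is not None else profile.time_point
    candidates = []  # (score, start, width, chrom)
    p_of_w = {w: shoulder / (shoulder + w) for w in widths}
    for chrom in dhs.chroms():
        if chrom not in profile.counts:
            continue
        fwd = profile.counts[chrom]["+"]
        rev = profile.counts[chrom]["-"]
        F = np.concatenate([[0], np.cumsum(fwd)])
        R = np.concatenate([[0], np.cumsum(rev)])
        for s, e in dhs.get(chrom):
            s, e = int(s), int(e)
            if e - s < min(widths) + 2 * shoulder:
                continue
            for w in widths:
                starts = np.arange(s + shoulder, e - shoulder - w + 1)
                if len(starts) == 0:
                    continue
                f_sl = F[starts] - F[starts - shoulder]
                f_w = F[starts + w] - F[starts]
                r_w = R[starts + w] - R[starts]
                r_sr = R[starts + w + shoulder] - R[starts + w]
                p = p_of_w[w]
                lp_f = stats.binom.logsf(f_sl - 1, f_sl + f_w, p) / _LN10
                lp_r = stats.binom.logsf(r_sr - 1, r_sr + r_w, p) / _LN10
                score = lp_f + lp_r
                keep = score < score_threshold
                for st, sc in zip(starts[keep], score[keep]):
                    candidates.append((float(sc), int(st), w, chrom))

    # greedy non-overlapping selection, best (lowest) score first
    candidates.sort(key=lambda c: (c[0], c[1]))
    occupied: dict[str, list[tuple[int, int]]] = {}
    out: list[Footprint] = []
    taken: dict[str, np.ndarray] = {}
    for sc, st, w, chrom in candidates:
        if chrom not in taken:
            n = len(profile.counts[chrom]["+"])
            taken[chrom] = np.zeros(n, dtype=bool)
        seg = taken[chrom][st:st + w]
        if seg.any():
            continue
        seg[:] = True
        out.append(Footprint(chrom, st, st + w, time_point=tp, score=sc))
    out.sort(key=lambda f: (f.chrom, f.start))
    return out


# ----------------------------------------------------------------- bias

def estimate_hexamer_bias(control: CutProfile, genome: GenomeSequence,
                          pseudocount: float = 1.0) -> HexamerBiasTable:
    """Relative cutting rate per hexamer from a deproteinated control.

    rate(h) = (cuts with context h + pc) / (genomic positions with context h
    + pc), normalized to mean 1 over hexamers observed in the genome.
    """
    if control.treatment != "deproteinated":
        raise ValueError("bias estimation requires the deproteinated control")
    if not genome.chroms or all(len(s) == 0 for s in genome.chroms.values()):
        raise ValueError("empty genome")
    cuts = np.zeros(4096)
    occ = np.zeros(4096)
    for chrom in control.chroms():
        codes = genome.encode(chrom)
        for strand in "+-":
            idx, valid = hexamer_indices(codes, strand)
            arr = control.counts[chrom][strand]
            v = valid & (np.arange(len(codes)) < len(arr))
            cuts += np.bincount(idx[v], weights=arr[v], minlength=4096)
            occ += np.bincount(idx[v], minlength=4096)
    rates = (cuts + pseudocount) / (occ + pseudocount)
    observed = occ > 0
    absent = [_index_to_hexamer(i) for i in np.nonzero(~observed)[0]]
    mean_rate = rates[observed].mean() if observed.any() else 1.0
    rates = rates / mean_rate
    rates[~observed] = 1.0
    return HexamerBiasTable(rates, pseudocount, control.library_size, absent)


def _index_to_hexamer(i: int) -> str:
    return "".join("ACGT"[(i >> (2 * (5 - k))) & 3] for k in range(6))


def expected_cut_rates(bias: HexamerBiasTable, genome: GenomeSequence,
                       chrom: str, start: int, end: int) -> np.ndarray:
    """Bias-expected per-base cut proportions over a region (sums to 1).

    The per-base weight averages the two strand contexts; bases whose context
    contains N (or runs off the chromosome) get weight 1.
    """
    if end - start < 1:
        raise ValueError("region width must be >= 1")
    weights = _bias_weights(bias, genome, chrom)[start:end]
    return weights / weights.sum()


def _bias_weights(bias: HexamerBiasTable, genome: GenomeSequence,
                  chrom: str) -> np.ndarray:
    codes = genome.encode(chrom)
    total = np.zeros(len(codes))
    for strand in "+-":
        idx, valid = hexamer_indices(codes, strand)
        w = np.ones(len(codes))
        w[valid] = bias.rates[idx[valid]]
        total += w
    return total / 2.0


# ----------------------------------------------------------------- FLR

def _em_two_gaussians(x: np.ndarray, seed: int = 0, max_iter: int = 300,
                      tol: float = 1e-9) -> MixtureFit:
    x = np.asarray(x, dtype=float)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x[:, None])
    mu = np.sort(km.cluster_centers_.ravel())  # lower mean = footprint comp
    sigma = np.full(2, max(x.std(), 1e-3))
    pi = np.full(2, 0.5)
    trace = []
    converged = False
    for _ in range(max_iter):
        logp = (np.log(pi)[None, :]
                + stats.norm.logpdf(x[:, None], mu[None, :], sigma[None, :]))
        m = logp.max(axis=1, keepdims=True)
        ll = float((m.ravel() + np.log(np.exp(logp - m).sum(axis=1))).sum())
        resp = np.exp(logp - m)
        resp /= resp.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0)
        pi = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, 1e-6))
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    order = np.argsort(mu)
    pi, mu, sigma = pi[order], mu[order], sigma[order]
    degenerate = bool(pi[0] < 1e-3 or pi[1] < 1e-3 or abs(mu[1] - mu[0]) < 1e-6)
    return MixtureFit((float(pi[0]), float(pi[1])), (float(mu[0]), float(mu[1])),
                      (float(sigma[0]), float(sigma[1])), trace, converged,
                      degenerate)


def flr_from_fit(fit: MixtureFit, x: np.ndarray) -> np.ndarray:
    """Posterior log-odds of the footprint (lower-mean) component."""
    x = np.asarray(x, dtype=float)
    if fit.degenerate:
        return np.full(len(x), -1.0)
    lf = np.log(fit.weights[0]) + stats.norm.logpdf(x, fit.means[0], fit.scales[0])
    lb = np.log(fit.weights[1]) + stats.norm.logpdf(x, fit.means[1], fit.scales[1])
    return lf - lb


def depletion_statistic(footprints: list[Footprint], profile: CutProfile,
                        bias: HexamerBiasTable, genome: GenomeSequence,
                        shoulder: int = 35, pseudo: float = 0.5) -> np.ndarray:
    """x = log((o_in/e_in)/(o_out/e_out)) per footprint (natural log)."""
    weights_cache: dict[str, np.ndarray] = {}
    xs = np.empty(len(footprints))
    for i, fp in enumerate(footprints):
        if fp.chrom not in weights_cache:
            weights_cache[fp.chrom] = _bias_weights(bias, genome, fp.chrom)
        w = weights_cache[fp.chrom]
        pooled = profile.pooled(fp.chrom)
        n = len(pooled)
        ls, le = max(0, fp.start - shoulder), fp.start
        rs, re = fp.end, min(n, fp.end + shoulder)
        o_in = pooled[fp.start:fp.end].sum()
        o_out = pooled[ls:le].sum() + pooled[rs:re].sum()
        e_in = w[fp.start:fp.end].sum()
        e_out = w[ls:le].sum() + w[rs:re].sum()
        xs[i] = np.log(((o_in + pseudo) / e_in) / ((o_out + pseudo) / e_out))
    return xs


def footprint_flr(footprints: list[Footprint], profile: CutProfile,
                  bias: HexamerBiasTable, genome: GenomeSequence,
                  shoulder: int = 35, seed: int = 0) -> tuple[list[Footprint], MixtureFit]:
    """Assign FLR to each footprint via the bias-corrected mixture model."""
    if len(footprints) < 20:
        raise ValueError("mixture fitting needs >= 20 footprints")
    xs = depletion_statistic(footprints, profile, bias, genome, shoulder)
    fit = _em_two_gaussians(xs, seed=seed)
    flrs = flr_from_fit(fit, xs)
    for fp, x, flr in zip(footprints, xs, flrs):
        fp.x = float(x)
        fp.flr = float(flr)
        fp.passed_filter = bool(flr >= 0)
    return footprints, fit


def filter_footprints(footprints: list[Footprint]) -> tuple[list[Footprint], dict]:
    """Drop FLR < 0 calls; report the removed fraction per time point."""
    retained = [fp for fp in footprints if fp.flr >= 0]
    report = {}
    tps = sorted({fp.time_point for fp in footprints}, key=lambda t: (t is None, t))
    for tp in tps:
        sub = [fp for fp in footprints if fp.time_point == tp]
        removed = sum(1 for fp in sub if not fp.flr >= 0)
        report[tp] = removed / len(sub) if sub else 0.0
    return retained, report


def extend_footprints(footprints: list[Footprint], pad: int = 4,
                      chrom_lengths: dict[str, int] | None = None) -> list[tuple[str, int, int]]:
    """Pad each footprint for motif scanning; records are not merged."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for fp in footprints:
        s = max(0, fp.start - pad)
        e = fp.end + pad
        if chrom_lengths is not None:
            e = min(e, chrom_lengths[fp.chrom])
        out.append((fp.chrom, s, e))
    return out
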