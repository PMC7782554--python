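"""Compartment, aggregate-contact, and boundary-profile analyses.

Megabase-scale A/B compartmentalization is read out from the leading
eigenvector (E1) of the distance-normalized cis correlation matrix of
a balanced bulk map, oriented by an external track (GC content or
activity).  Sparse single-cell maps are too shallow for direct
eigenvector analysis, so their compartment signal is aggregated over a
bulk-derived E1 mask into 5×5 saddle plots.  Long-range looping
between scored anchor regions is aggregated into average-loop
heatmaps.  State-resolved contact-probability curves and epigenetic
track profiles around TAD-boundary classes complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import PcCurve, SparseContactMap

__all__ = [
    "BinStateTrack",
    "cis_eigenvector",
    "saddle_profile",
    "average_loop",
    "classify_bins",
    "pc_by_state",
    "boundary_track_profile",
]


def _observed_over_expected(dense: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean (0 where the diagonal is empty)."""
    n = dense.shape[0]
    oe = np.zeros_like(dense, dtype=float)
    for k in range(-n + 1, n):
        diag = np.diagonal(dense, k)
        mu = diag.mean()
        if mu > 0:
            idx = np.arange(max(0, -k), min(n, n - k))
            oe[idx, idx + k] = diag / mu
    return oe


def cis_eigenvector(
    cmap: SparseContactMap,
    orientation_track: dict[str, np.ndarray] | np.ndarray,
    weights: dict[str, np.ndarray] | None = None,
    min_informative_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Leading eigenvector (E1) of the cis O/E correlation matrix.

    For each chromosome: balance (if ``weights`` given), normalize by
    expected-at-distance, take the Pearson correlation matrix over
    informative bins, extract the leading eigenvector, and flip its
    sign so it correlates positively with the orientation track.
    Masked bins get NaN; chromosomes with fewer than
    ``min_informative_bins`` informative bins get an all-NaN track.
    """
    out: dict[str, np.ndarray] = {}
    for chrom in cmap.chromosomes:
        n = cmap.chrom_bins[chrom]
        track = (
            orientation_track[chrom]
            if isinstance(orientation_track, dict)
            else orientation_track
        )
        dense = cmap.to_dense(chrom)
        if weights is not None:
            w = np.nan_to_num(weights[chrom], nan=0.0)
            dense = dense * np.outer(w, w)
        informative = dense.sum(axis=1) > 0
        e1 = np.full(n, np.nan)
        if informative.sum() >= min_informative_bins:
            sub = dense[np.ix_(informative, informative)]
            oe = _observed_over_expected(sub)
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(oe)
            corr = np.nan_to_num(corr)
            vals, vecs = np.linalg.eigh(corr)
            v = vecs[:, -1]
            t = np.nan_to_num(np.asarray(track, float)[informative])
            if np.std(t) > 0 and np.corrcoef(v, t)[0, 1] < 0:
                v = -v
            e1[informative] = v
        out[chrom] = e1
    return out


def saddle_profile(
    cmap: SparseContactMap,
    e1: np.ndarray,
    n_groups: int = 5,
    chrom: str | None = None,
    norm: str = "oe",
) -> np.ndarray:
    """5×5 saddle: contact enrichment between E1-ranked bin groups.

    Bins with defined E1 are ranked ascending and cut into
    ``n_groups`` equal-size groups; the matrix entry (g, h) is the
    log2 of the mean (distance-normalized if ``norm='oe'``) contact
    between the groups relative to the genome-wide mean.
    """
    ch = chrom or cmap.chromosomes[0]
    dense = cmap.to_dense(ch)
    n = dense.shape[0]
    e1 = np.asarray(e1, float)
    valid = np.flatnonzero(~np.isnan(e1))
    if len(valid) < n_groups:
        raise ValueError("fewer informative bins than saddle groups")
    if norm == "oe":
        # expected-at-distance surface; enrichment per block is the
        # ratio of sums Σobs/Σexp (robust on sparse single-cell maps,
        # unlike a mean of per-pixel O/E)
        exp = np.zeros_like(dense)
        for k in range(-n + 1, n):
            mu = np.diagonal(dense, k).mean()
            idx = np.arange(max(0, -k), min(n, n - k))
            exp[idx, idx + k] = mu
    else:
        exp = np.ones_like(dense)
    order = valid[np.argsort(e1[valid], kind="stable")]
    groups = np.array_split(order, n_groups)
    ratios = np.zeros((n_groups, n_groups))
    for a in range(n_groups):
        for b in range(n_groups):
            ix = np.ix_(groups[a], groups[b])
            num, den = dense[ix].sum(), exp[ix].sum()
            ratios[a, b] = num / den if den > 0 else np.nan
    overall = np.nanmean(ratios)
    return np.log2((ratios + 1e-12) / (overall + 1e-12))


def average_loop(
    cmap: SparseContactMap,
    anchors: np.ndarray,
    scores: np.ndarray | None = None,
    window: int = 600_000,
    min_sep: int = 600_000,
    max_intervening: int = 50,
    top_n: int | None = 1000,
    chrom: str | None = None,
) -> np.ndarray:
    """Aggregate contact heatmap over pairs of scored anchor positions.

    Anchors (bp positions on one chromosome, optionally scored by a
    track) are reduced to the ``top_n`` highest-scoring ones; pairs at
    genomic separation > ``min_sep`` and separated by at most
    ``max_intervening`` other anchors qualify.  For each pair the
    square ``window`` centered on (pos_i, pos_j) is snipped and summed;
    the result is log10(sum + 1).  Invariant to anchor-list order.
    """
    ch = chrom or cmap.chromosomes[0]
    dense = cmap.to_dense(ch)
    bs = cmap.binsize
    anchors = np.asarray(anchors)
    if scores is not None:
        scores = np.asarray(scores)
        order = np.argsort(-scores, kind="stable")
        anchors = anchors[order[: top_n or len(anchors)]]
    elif top_n is not None:
        anchors = anchors[:top_n]
    anchors = np.sort(anchors)
    half = (window // bs) // 2
    size = 2 * half + 1
    acc = np.zeros((size, size))
    n_pairs = 0
    n = dense.shape[0]
    for ai in range(len(anchors)):
        for aj in range(ai + 1, min(len(anchors), ai + max_intervening + 2)):
            # aj - ai - 1 anchors lie strictly between the pair
            if aj - ai - 1 > max_intervening:
                break
            if anchors[aj] - anchors[ai] <= min_sep:
                continue
            bi, bj = int(anchors[ai] // bs), int(anchors[aj] // bs)
            if bi - half < 0 or bj + half >= n:
                continue
            acc += dense[bi - half : bi + half + 1, bj - half : bj + half + 1]
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no qualifying anchor pairs")
    return np.log10(acc + 1.0)


@dataclass
class BinStateTrack:
    """Per-bin chromatin state and expression-group labels."""

    state: np.ndarray  # 'active' | 'inactive' | 'polycomb' | 'unannotated'
    expression_group: np.ndarray | None = None


def classify_bins(
    state_fractions: dict[str, np.ndarray],
    expression: np.ndarray | None = None,
    threshold: float = 0.5,
) -> BinStateTrack:
    """Assign chromatin states (and expression groups) to bins.

    ``state_fractions`` maps 'active'/'inactive'/'polycomb' to the
    per-bin fraction of the corresponding chromatin colors; the first
    rule whose fraction exceeds ``threshold`` wins (active, then
    inactive, then polycomb); the rest is unannotated.  Expression
    groups: 'zero' for no expression, then percentile bands of the
    full distribution (zero-inflated, so the first band starts where
    the zeros end), '38.1-40', '40-60', '60-80', 'top20'.
    """
    n = len(next(iter(state_fractions.values())))
    state = np.full(n, "unannotated", dtype="<U11")
    for name in ("active", "inactive", "polycomb"):
        frac = np.asarray(state_fractions.get(name, np.zeros(n)))
        state[(state == "unannotated") & (frac > threshold)] = name
    groups = None
    if expression is not None:
        expr = np.asarray(expression, float)
        groups = np.full(n, "zero", dtype="<U8")
        from scipy.stats import rankdata

        pr = rankdata(expr, method="average") / len(expr) * 100.0
        nz = expr > 0
        groups[nz & (pr <= 40)] = "38.1-40"
        groups[nz & (pr > 40) & (pr <= 60)] = "40-60"
        groups[nz & (pr > 60) & (pr <= 80)] = "60-80"
        groups[nz & (pr > 80)] = "top20"
    return BinStateTrack(state=state, expression_group=groups)


def pc_by_state(
    maps: list[SparseContactMap] | SparseContactMap,
    states: np.ndarray,
    chrom: str | None = None,
) -> dict[str, PcCurve]:
    """P_c(s) restricted to bin pairs sharing a chromatin state.

    Counts at distance s include only contacts whose two bins carry
    the same state label; single-cell normalization divides by the
    number of covered bins of that state (union over experiments).
    States with fewer than two bins yield an empty curve.
    """
    if isinstance(maps, SparseContactMap):
        maps = [maps]
    ch = chrom or maps[0].chromosomes[0]
    n = maps[0].chrom_bins[ch]
    binsize = maps[0].binsize
    states = np.asarray(states)
    covered = np.zeros(n, dtype=bool)
    for m in maps:
        i, j, _ = m.triplets(ch)
        covered[i] = True
        covered[j] = True
    out: dict[str, PcCurve] = {}
    for lab in np.unique(states):
        sel = states == lab
        if sel.sum() < 2:
            out[str(lab)] = PcCurve(
                s=np.zeros(0), pc=np.zeros(0), mode="single_cell"
            )
            continue
        counts = np.zeros(n)
        for m in maps:
            i, j, c = m.triplets(ch)
            both = sel[i] & sel[j]
            np.add.at(counts, (j - i)[both], c[both])
        denom = max(int((covered & sel).sum()), 1)
        s = np.arange(1, n) * binsize
        out[str(lab)] = PcCurve(s=s, pc=counts[1:] / denom, mode="single_cell")
    return out


def boundary_track_profile(
    track: np.ndarray,
    boundary_sets: dict[str, np.ndarray],
    flank_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Mean track value around boundaries, per boundary class.

    ``track`` is binned at map resolution; ``boundary_sets`` maps class
    names (bulk / merged / stable / unstable / cell-specific / TAD bins
    / random) to bin-grid boundary positions.  Returns per class the
    mean profile over offsets −flank..+flank (±100 kb at 10-kb bins by
    default); boundaries too close to the chromosome ends are skipped.
    """
    track = np.asarray(track, float)
    n = len(track)
    out: dict[str, np.ndarray] = {}
    for name, edges in boundary_sets.items():
        profile = np.zeros(2 * flank_bins + 1)
        count = 0
        for e in np.asarray(edges, int):
            b = min(max(e, 0), n - 1)
            if b - flank_bins < 0 or b + flank_bins >= n:
                continue
            profile += track[b - flank_bins : b + flank_bins + 1]
            count += 1
        out[name] = profile / count if count else np.full(2 * flank_bins + 1, np.nan)
    return out
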