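"""MS / MSS random-graph null models and window-Poisson statistics.

A sparse single-cell contact map on N bins is modeled as a random graph
with independent links.  Two nulls:

* MS (marginal scaling): link probability depends only on genomic
  separation, p_ij ∝ P_c(|i−j|), normalized so that the expected number
  of links equals the observed contact count N_c.
* MSS (marginal scaling + stickiness): p_ij ∝ k_i k_j P_c(|i−j|) with a
  per-bin "stickiness" k_i — a non-selective affinity — fitted so the
  model's expected coverage matches the observed per-bin coverage.

The stickiness fit solves k̃_i = k_i α_i with activity
α_i = (1/Z) Σ_j k_j P_c(|i−j|), Z = (1/N_c) Σ_{i<j} k_i k_j P_c(|i−j|),
by iterative approximation starting from k⁽⁰⁾ = k̃.

Whether observed maps are distinguishable from these nulls is tested by
counting contacts in non-overlapping triangular windows along the main
diagonal and applying a χ² goodness-of-fit test against the Poisson
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .maps import SparseContactMap

__all__ = [
    "NullModelSpec",
    "StickinessFit",
    "ms_probabilities",
    "mss_probabilities",
    "fit_stickiness",
    "sample_null_map",
    "resample_conditioned_on_marginals",
    "window_counts",
    "poisson_gof",
]


@dataclass
class NullModelSpec:
    """Link-probability matrix with its defining ingredients."""

    n_bins: int
    n_contacts: float
    p: np.ndarray  # dense symmetric, zero diagonal
    stickiness: np.ndarray | None = None
    capped: bool = False


@dataclass
class StickinessFit:
    """Result of the stickiness fixed-point iteration."""

    coverage: np.ndarray  # observed k̃_i (zero-coverage bins included)
    stickiness: np.ndarray  # fitted k_i (0 where excluded)
    activity: np.ndarray
    iterations: int
    residual: float
    excluded: np.ndarray  # bool mask of zero-coverage bins


def _distance_matrix(pc_by_bin: np.ndarray, n: int) -> np.ndarray:
    """C_ij = P_c(|i−j|) for i != j, 0 on the diagonal."""
    pc = np.asarray(pc_by_bin, dtype=float)
    if len(pc) < n:
        pc = np.pad(pc, (0, n - len(pc)))
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    c = pc[d]
    np.fill_diagonal(c, 0.0)
    return c


def ms_probabilities(pc_by_bin: np.ndarray, n: int, n_contacts: float) -> NullModelSpec:
    """MS link probabilities p_ij = P_c(|i−j|) N_c / Σ_s (N−s) P_c(s).

    ``pc_by_bin[d]`` is P_c at separation d bins (index 0 unused).
    The pre-cap sum over i<j equals ``n_contacts`` exactly; entries are
    then capped at 1 (flagged via ``capped``).
    """
    if n_contacts < 0:
        raise ValueError("n_contacts must be >= 0")
    if n_contacts > n * (n - 1) / 2:
        raise ValueError("n_contacts exceeds the number of available pairs")
    c = _distance_matrix(pc_by_bin, n)
    denom = np.triu(c, 1).sum()
    if denom == 0:
        if n_contacts > 0:
            raise ValueError("P_c is identically zero but n_contacts > 0")
        return NullModelSpec(n, 0.0, np.zeros((n, n)))
    p = c * (n_contacts / denom)
    capped = bool((p > 1).any())
    return NullModelSpec(n, float(n_contacts), np.minimum(p, 1.0), capped=capped)


def mss_probabilities(
    stickiness: np.ndarray, pc_by_bin: np.ndarray, n_contacts: float
) -> NullModelSpec:
    """MSS link probabilities p_ij = k_i k_j P_c(|i−j|) N_c / Z·N_c.

    Scale-invariant in k; reduces to the MS model for uniform k.
    """
    k = np.asarray(stickiness, dtype=float)
    n = len(k)
    if (k < 0).any():
        raise ValueError("stickiness must be non-negative")
    if n_contacts > n * (n - 1) / 2:
        raise ValueError("n_contacts exceeds the number of available pairs")
    c = _distance_matrix(pc_by_bin, n)
    kk = np.outer(k, k) * c
    denom = np.triu(kk, 1).sum()
    if denom == 0:
        if n_contacts > 0:
            raise ValueError("degenerate model: all pair weights zero")
        return NullModelSpec(n, 0.0, np.zeros((n, n)), stickiness=k)
    p = kk * (n_contacts / denom)
    capped = bool((p > 1).any())
    return NullModelSpec(
        n, float(n_contacts), np.minimum(p, 1.0), stickiness=k, capped=capped
    )


def fit_stickiness(
    coverage: np.ndarray | SparseContactMap,
    pc_by_bin: np.ndarray,
    chrom: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    damping: float = 0.0,
) -> StickinessFit:
    """Fit per-bin stickiness from observed coverage by fixed-point iteration.

    ``coverage`` is the per-bin contact count k̃ of the merged map (or a
    map, from which the marginal of one chromosome is taken).  Iterates
    k ← k̃ / α(k) with α recomputed each step; ``damping`` in [0,1)
    mixes in the previous iterate.  The plain iteration can enter a
    2-cycle on sparse coverage profiles; if it fails to converge with
    damping off, one damped retry (0.5) is attempted before raising.
    Zero-coverage bins are excluded from the fit and flagged.
    """
    if isinstance(coverage, SparseContactMap):
        ch = chrom or coverage.chromosomes[0]
        n = coverage.chrom_bins[ch]
        kt = np.zeros(n)
        i, j, c = coverage.triplets(ch)
        np.add.at(kt, i, c)
        np.add.at(kt, j, c)
    else:
        kt = np.asarray(coverage, dtype=float)
        n = len(kt)
    excluded = kt <= 0
    active = ~excluded
    n_c = kt.sum() / 2.0
    c = _distance_matrix(pc_by_bin, n)
    c = c[np.ix_(active, active)]
    kta = kt[active]
    def iterate(damp):
        k = kta.copy()
        alpha = np.ones_like(k)
        resid = np.inf
        for it in range(1, max_iter + 1):
            s = c @ k  # Σ_j k_j P_c(|i−j|)
            z = (k @ s) / 2.0 / n_c  # Z = (1/N_c) Σ_{i<j} k_i k_j C_ij
            alpha = s / z
            resid = np.abs(kta - k * alpha).max()
            if resid < tol:
                return k, alpha, it, resid
            k_new = kta / alpha
            if damp:
                k_new = (1 - damp) * k_new + damp * k
            k = k_new
        return None, alpha, max_iter, resid

    k, alpha, it, resid = iterate(damping)
    if k is None and damping == 0.0:
        k, alpha, it, resid = iterate(0.5)
    if k is None:
        raise RuntimeError(
            f"stickiness iteration did not converge: residual {resid:.3e}"
        )
    k_full = np.zeros(n)
    k_full[active] = k
    a_full = np.zeros(n)
    a_full[active] = alpha
    return StickinessFit(
        coverage=kt,
        stickiness=k_full,
        activity=a_full,
        iterations=it,
        residual=float(resid),
        excluded=excluded,
    )


def sample_null_map(
    model: NullModelSpec,
    seed: int | None = None,
    n_maps: int = 1,
    binsize: int = 10_000,
    chrom: str = "chr1",
) -> list[SparseContactMap]:
    """Draw independent-Bernoulli adjacency matrices from ``model.p``."""
    rng = np.random.default_rng(seed)
    n = model.n_bins
    iu, ju = np.triu_indices(n, 1)
    pu = model.p[iu, ju]
    out = []
    for _ in range(n_maps):
        hit = rng.random(len(pu)) < pu
        out.append(
            SparseContactMap(
                binsize,
                {chrom: n},
                {chrom: (iu[hit], ju[hit], np.ones(int(hit.sum()), dtype=np.int64))},
                metadata={"null_model": "mss" if model.stickiness is not None else "ms"},
            )
        )
    return out


def resample_conditioned_on_marginals(
    marginals: np.ndarray,
    pc_by_bin: np.ndarray,
    n_contacts: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-weighted stub matching preserving per-bin marginals exactly.

    Each bin contributes ``marginals[i]`` contact ends ("stubs"); stubs
    are paired sequentially, partner drawn with probability
    ∝ residual_ends_j · P_c(|i−j|).  Realizes Σ marg / 2 contacts with
    the exact observed marginal distribution and an approximate P_c(s).
    """
    rng = rng or np.random.default_rng()
    marg = np.asarray(marginals, dtype=np.int64).copy()
    n = len(marg)
    pc = np.asarray(pc_by_bin, dtype=float)
    if len(pc) < n:
        pc = np.pad(pc, (0, n - len(pc)))
    ii, jj = [], []
    for _ in range(n_contacts):
        nz = np.flatnonzero(marg)
        if len(nz) == 0:
            break
        # pick the source stub uniformly over remaining ends
        i = rng.choice(nz, p=marg[nz] / marg[nz].sum())
        marg[i] -= 1
        w = marg.astype(float) * pc[np.abs(np.arange(n) - i)]
        w[i] = 0.0  # no self-contacts
        tot = w.sum()
        if tot == 0:
            # fall back to any bin with remaining ends
            w = marg.astype(float)
            w[i] = 0.0
            tot = w.sum()
            if tot == 0:
                marg[i] += 1
                break
        j = rng.choice(n, p=w / tot)
        marg[j] -= 1
        ii.append(min(i, j))
        jj.append(max(i, j))
    return np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64)


def window_counts(
    cmap: SparseContactMap | np.ndarray, w: int, chrom: str | None = None
) -> np.ndarray:
    """Contacts in non-overlapping W-bin triangular windows on the diagonal.

    The chromosome is tiled by windows ``[kW, (k+1)W)``; a window's
    count is the number of contacts with both ends inside it (the
    isosceles triangle with base on the main diagonal).  The incomplete
    tail window is discarded.  W > N yields an empty array.
    """
    if w < 2:
        raise ValueError("window size must be >= 2 bins")
    if isinstance(cmap, SparseContactMap):
        ch = chrom or cmap.chromosomes[0]
        n = cmap.chrom_bins[ch]
        i, j, c = cmap.triplets(ch)
    else:
        dense = np.asarray(cmap)
        n = dense.shape[0]
        iu, ju = np.triu_indices(n, 1)
        mask = dense[iu, ju] != 0
        i, j, c = iu[mask], ju[mask], dense[iu, ju][mask]
    n_win = n // w
    counts = np.zeros(n_win, dtype=np.int64)
    if n_win == 0:
        return counts
    wi = i // w
    same = (wi == j // w) & (wi < n_win)
    np.add.at(counts, wi[same], c[same].astype(np.int64))
    return counts


def poisson_gof(counts: np.ndarray, min_expected: float = 5.0) -> dict:
    """χ² goodness of fit of window counts against Poisson(λ̂).

    λ̂ is the MLE (sample mean).  The count histogram's cells are merged
    from both tails until every expected cell count is >= ``min_expected``;
    dof = cells − 2 (one for the total, one for λ̂).  Returns λ̂, the χ²
    statistic, dof, and the upper-tail p-value.  Degenerate inputs (all
    counts equal, or too few mergeable cells) return p = 1 with a flag.
    """
    x = np.asarray(counts, dtype=np.int64)
    if len(x) < 20:
        raise ValueError("need at least 20 windows for the GOF test")
    lam = float(x.mean())
    if np.all(x == x[0]):
        return {"lambda": lam, "chi2": 0.0, "dof": 0, "p_value": 1.0, "degenerate": True}
    kmax = int(x.max())
    obs = np.bincount(x, minlength=kmax + 1).astype(float)
    exp = stats.poisson.pmf(np.arange(kmax + 1), lam) * len(x)
    # open upper tail
    exp[-1] += stats.poisson.sf(kmax, lam) * len(x)
    # merge adjacent histogram cells left-to-right until each carries
    # expected mass >= min_expected; fold the remainder into the last cell
    cells_obs, cells_exp = [], []
    acc_o = acc_e = 0.0
    for o_k, e_k in zip(obs, exp):
        acc_o += o_k
        acc_e += e_k
        if acc_e >= min_expected:
            cells_obs.append(acc_o)
            cells_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and cells_exp:
        cells_obs[-1] += acc_o
        cells_exp[-1] += acc_e
    dof = len(cells_exp) - 2
    if dof < 1:
        return {"lambda": lam, "chi2": 0.0, "dof": max(dof, 0), "p_value": 1.0, "degenerate": True}
    o = np.asarray(cells_obs)
    e = np.asarray(cells_exp)
    chi2 = float(((o - e) ** 2 / e).sum())
    return {
        "lambda": lam,
        "chi2": chi2,
        "dof": dof,
        "p_value": float(stats.chi2.sf(chi2, dof)),
        "degenerate": False,
    }
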