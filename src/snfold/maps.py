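"""Binned sparse contact maps and single-cell summary statistics.

The central container is :class:`SparseContactMap`: a symmetric binned
contact matrix stored as upper-triangle triplets ``(i, j, count)`` with
``i <= j``, one triplet set per chromosome, at a fixed bin size.  Only
intra-chromosomal (cis) contacts are binned — every downstream analysis
here is cis-based.

Statistics implemented: the contact-probability decay P_c(s) in bulk
and single-cell normalizations, coverage summaries, the
recovered-contact percentage against the restriction-fragment pool,
per-distance and marginal-preserving shuffles, and iterative-correction
balancing for bulk maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomeSpec, RestrictionMap

__all__ = [
    "SparseContactMap",
    "PcCurve",
    "bin_contacts",
    "merge_maps",
    "pc_curve",
    "percent_recovered",
    "coverage_stats",
    "shuffle_map",
    "balance_ice",
]


class SparseContactMap:
    """Symmetric binned contact matrix as upper-triangle triplets.

    Parameters
    ----------
    binsize
        Bin size in bp.
    chrom_bins
        ``{chrom: number of bins}``.
    triplets
        ``{chrom: (i, j, count)}`` integer arrays with ``i <= j``;
        duplicate pairs are summed on construction.
    metadata
        Free-form; conventionally carries ``cell_id`` and
        ``diagonals_removed``.
    """

    def __init__(
        self,
        binsize: int,
        chrom_bins: Mapping[str, int],
        triplets: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        metadata: dict | None = None,
    ):
        self.binsize = int(binsize)
        self.chrom_bins = {c: int(n) for c, n in chrom_bins.items()}
        self.metadata = dict(metadata or {})
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        triplets = triplets or {}
        for chrom in self.chrom_bins:
            if chrom in triplets:
                i, j, c = (np.asarray(a) for a in triplets[chrom])
                self._set(chrom, i, j, c)
            else:
                z = np.zeros(0, dtype=np.int64)
                self._data[chrom] = (z, z.copy(), z.copy())

    def _set(self, chrom: str, i, j, c) -> None:
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        c = np.asarray(c)
        c = c.astype(np.int64) if np.issubdtype(c.dtype, np.integer) else c.astype(np.float64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        n = self.chrom_bins[chrom]
        if len(lo) and (lo.min() < 0 or hi.max() >= n):
            raise ValueError(f"bin index out of range for {chrom} (n={n})")
        # merge duplicates
        key = lo * n + hi
        order = np.argsort(key, kind="stable")
        key, lo, hi, c = key[order], lo[order], hi[order], c[order]
        uniq, start = np.unique(key, return_index=True)
        csum = np.add.reduceat(c, start) if len(c) else c
        self._data[chrom] = (lo[start], hi[start], csum)

    # -- accessors ---------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_bins)

    def triplets(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data[chrom]

    def n_contacts(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self._data[chrom][2].sum())
        return int(sum(t[2].sum() for t in self._data.values()))

    def to_dense(self, chrom: str) -> np.ndarray:
        n = self.chrom_bins[chrom]
        m = np.zeros((n, n), dtype=np.float64)
        i, j, c = self._data[chrom]
        m[i, j] = c
        m[j, i] = c
        return m

    @classmethod
    def from_dense(
        cls, matrix: np.ndarray, binsize: int, chrom: str = "chr1", metadata=None
    ) -> "SparseContactMap":
        m = np.asarray(matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        iu, ju = np.triu_indices(m.shape[0])
        mask = m[iu, ju] != 0
        return cls(
            binsize,
            {chrom: m.shape[0]},
            {chrom: (iu[mask], ju[mask], m[iu, ju][mask])},
            metadata=metadata,
        )

    def copy(self) -> "SparseContactMap":
        return SparseContactMap(
            self.binsize,
            self.chrom_bins,
            {c: tuple(a.copy() for a in t) for c, t in self._data.items()},
            metadata=dict(self.metadata),
        )

    # -- text I/O ----------------------------------------------------------

    def write_tsv(self, path) -> None:
        """TSV triplet dialect: chrom, bin_i, bin_j, count (+ header)."""
        with open(path, "w") as fh:
            fh.write(f"# binsize={self.binsize}\n")
            for chrom, n in self.chrom_bins.items():
                fh.write(f"# chrom={chrom}\tbins={n}\n")
            fh.write("chrom\tbin1\tbin2\tcount\n")
            for chrom in self.chromosomes:
                i, j, c = self._data[chrom]
                for a, b, v in zip(i, j, c):
                    fh.write(f"{chrom}\t{a}\t{b}\t{v}\n")

    @classmethod
    def read_tsv(cls, path) -> "SparseContactMap":
        binsize = None
        chrom_bins: dict[str, int] = {}
        rows: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# binsize="):
                    binsize = int(line.split("=", 1)[1])
                elif line.startswith("# chrom="):
                    part = line[2:].split("\t")
                    chrom_bins[part[0].split("=", 1)[1]] = int(part[1].split("=", 1)[1])
                elif line.startswith(("#", "chrom\t")) or not line:
                    continue
                else:
                    chrom, a, b, v = line.split("\t")
                    rows.setdefault(chrom, []).append((int(a), int(b), int(v)))
        if binsize is None:
            raise ValueError("missing binsize header")
        trip = {
            c: tuple(np.array(col) for col in zip(*r)) if r else None
            for c, r in rows.items()
        }
        return cls(binsize, chrom_bins, {c: t for c, t in trip.items() if t})


@dataclass
class PcCurve:
    """Contact probability vs genomic distance.

    ``s`` is the distance grid in bp (> 0), ``pc`` the probability
    estimate, ``mode`` the normalization used ('bulk' or 'single_cell').
    """

    s: np.ndarray
    pc: np.ndarray
    mode: str = "bulk"

    def at_bins(self, binsize: int) -> np.ndarray:
        """P_c indexed by bin separation (index d <-> s = d*binsize)."""
        out = np.zeros(int(self.s.max() // binsize) + 1)
        idx = (self.s // binsize).astype(int)
        out[idx] = self.pc
        return out


# ---------------------------------------------------------------------------


def bin_contacts(
    contacts: Iterable,
    binsize: int,
    chrom_lengths: Mapping[str, int],
    drop_diagonals: int = 0,
    metadata: dict | None = None,
) -> SparseContactMap:
    """Bin cis contacts at ``binsize``; drop short diagonals.

    ``contacts`` yields objects with ``chrom1, pos1, chrom2, pos2``
    attributes (or 4-tuples).  Bin index = floor(pos / binsize).
    ``drop_diagonals`` = d removes |i−j| <= d: single-cell maps use
    d=0 (the main diagonal: self-interacting bins, dangling ends,
    self-circles), bulk maps use d=1.  Trans contacts are ignored.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    chrom_bins = {c: int(np.ceil(L / binsize)) for c, L in chrom_lengths.items()}
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_bins}
    for rec in contacts:
        if hasattr(rec, "chrom1"):
            c1, p1, c2, p2 = rec.chrom1, rec.pos1, rec.chrom2, rec.pos2
        else:
            c1, p1, c2, p2 = rec[:4]
        if c1 != c2 or c1 not in per_chrom:
            continue
        i, j = int(p1) // binsize, int(p2) // binsize
        if abs(i - j) <= drop_diagonals:
            continue
        per_chrom[c1].append((min(i, j), max(i, j)))
    trip = {}
    for chrom, pairs in per_chrom.items():
        if pairs:
            arr = np.asarray(pairs, dtype=np.int64)
            trip[chrom] = (arr[:, 0], arr[:, 1], np.ones(len(arr), dtype=np.int64))
    meta = dict(metadata or {})
    meta["diagonals_removed"] = drop_diagonals
    return SparseContactMap(binsize, chrom_bins, trip, metadata=meta)


def merge_maps(maps: Sequence[SparseContactMap]) -> SparseContactMap:
    """Elementwise sum of identically binned maps."""
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.binsize != first.binsize or m.chrom_bins != first.chrom_bins:
            raise ValueError("maps must share binsize and chromosomes")
    trip = {}
    for chrom in first.chromosomes:
        i = np.concatenate([m.triplets(chrom)[0] for m in maps])
        j = np.concatenate([m.triplets(chrom)[1] for m in maps])
        c = np.concatenate([m.triplets(chrom)[2] for m in maps])
        trip[chrom] = (i, j, c)
    return SparseContactMap(
        first.binsize, first.chrom_bins, trip, metadata={"merged_from": len(maps)}
    )


def _covered_bins(maps: Sequence[SparseContactMap], chrom: str) -> np.ndarray:
    """Union over maps of bins with >= 1 contact at any distance."""
    n = maps[0].chrom_bins[chrom]
    covered = np.zeros(n, dtype=bool)
    for m in maps:
        i, j, c = m.triplets(chrom)
        covered[i] = True
        covered[j] = True
    return covered


def pc_curve(
    maps: Sequence[SparseContactMap] | SparseContactMap,
    mode: str = "single_cell",
    step: int | None = None,
) -> PcCurve:
    """Contact probability P_c(s) over genomic distance.

    bulk mode: mean contact count per bin pair at each separation
    (count at distance d divided by the number of pairs N−d, summed
    over chromosomes).  single_cell mode: total count at distance s
    normalized by the number of bins covered by at least one contact in
    at least one of the experiments, at any distance — robust to the
    missing data of sparse cells.

    ``step`` (bp) coarsens the distance grid by summing counts within
    each step window; defaults to one bin.
    """
    if isinstance(maps, SparseContactMap):
        maps = [maps]
    if not maps:
        raise ValueError("need at least one map")
    binsize = maps[0].binsize
    step = step or binsize
    if step % binsize:
        raise ValueError("step must be a multiple of binsize")
    max_bins = max(maps[0].chrom_bins.values())
    counts = np.zeros(max_bins, dtype=np.float64)
    npairs = np.zeros(max_bins, dtype=np.float64)
    n_covered = 0
    for chrom in maps[0].chromosomes:
        n = maps[0].chrom_bins[chrom]
        for m in maps:
            i, j, c = m.triplets(chrom)
            d = j - i
            np.add.at(counts, d, c)
        d_grid = np.arange(n)
        npairs[:n] += (n - d_grid) * len(maps)
        n_covered += int(_covered_bins(maps, chrom).sum())
    fac = step // binsize
    # drop separation 0 (self-distance), then window the rest by `step`
    counts, npairs = counts[1:], npairs[1:]
    starts = np.arange(0, max_bins - 1, fac)
    csum = np.add.reduceat(counts, starts)
    psum = np.add.reduceat(npairs, starts)
    # window [1+k·fac, 1+(k+1)·fac): label by its central separation
    s_grid = (starts + 1 + (fac - 1) / 2.0) * binsize
    if mode == "bulk":
        with np.errstate(invalid="ignore", divide="ignore"):
            pc = np.where(psum > 0, csum / psum, 0.0)
    elif mode == "single_cell":
        denom = max(n_covered, 1)
        pc = csum / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PcCurve(s=s_grid, pc=pc, mode=mode)


def percent_recovered(
    n_contacts: int,
    restriction_map: RestrictionMap | None = None,
    genome: GenomeSpec | None = None,
    fragment_counts: Mapping[str, int] | None = None,
    copy_numbers: Mapping[str, int] | None = None,
) -> float:
    """Percentage of recovered contacts out of the theoretical maximum.

    Each restriction fragment has two ends, so with fragment valency
    2 per copy the upper limit of unique contacts per nucleus equals
    the fragment pool size Σ_chrom n_fragments × copy_number.  The pool
    can come from a :class:`RestrictionMap` + :class:`GenomeSpec`, or
    from explicit per-chromosome fragment counts and copy numbers.
    """
    if fragment_counts is None:
        if restriction_map is None:
            raise ValueError("need a restriction map or explicit fragment counts")
        fragment_counts = {
            c: restriction_map.n_fragments(c) for c in restriction_map.chromosomes
        }
    if copy_numbers is None:
        if genome is not None:
            copy_numbers = {c: genome.copy_number(c) for c in fragment_counts}
        else:
            copy_numbers = {c: 2 for c in fragment_counts}
    pool = sum(int(fragment_counts[c]) * int(copy_numbers.get(c, 2)) for c in fragment_counts)
    if pool == 0:
        raise ValueError("empty fragment pool")
    return 100.0 * n_contacts / pool


def coverage_stats(cmap: SparseContactMap) -> dict[str, float]:
    """Coverage summary over *all* reference bins.

    Returns percentage of bins with >= 1 contact, percentage with > 1
    contact, and the mean number of contacts per bin (each contact
    counts toward both its bins).
    """
    total_bins = sum(cmap.chrom_bins.values())
    if total_bins == 0:
        return {"pct_covered": 0.0, "pct_multi": 0.0, "mean_per_bin": 0.0}
    n_cov = n_multi = 0
    total = 0
    for chrom in cmap.chromosomes:
        n = cmap.chrom_bins[chrom]
        marg = np.zeros(n, dtype=np.int64)
        i, j, c = cmap.triplets(chrom)
        np.add.at(marg, i, c)
        np.add.at(marg, j, c)
        n_cov += int((marg >= 1).sum())
        n_multi += int((marg > 1).sum())
        total += int(marg.sum())
    return {
        "pct_covered": 100.0 * n_cov / total_bins,
        "pct_multi": 100.0 * n_multi / total_bins,
        "mean_per_bin": total / total_bins,
    }


def shuffle_map(
    cmap: SparseContactMap, mode: str = "per_distance", seed: int | None = None
) -> SparseContactMap:
    """Randomize contact positions under a conservation constraint.

    per_distance: for every chromosome and genomic distance d, the d-th
    diagonal's contacts are redistributed uniformly over the N−d
    positions of that diagonal (the per-diagonal count histogram is
    exactly conserved) — the control used both for map statistics and
    for polymer-model inputs.

    marginal+scaling: MSS-style resampling — per-bin marginals are
    preserved via stickiness fitted to the map itself and P_c(s) is
    approximated; the realized contact count matches the original.
    """
    rng = np.random.default_rng(seed)
    out = {}
    if mode == "per_distance":
        for chrom in cmap.chromosomes:
            n = cmap.chrom_bins[chrom]
            i, j, c = cmap.triplets(chrom)
            new_i, new_j = [], []
            d_all = np.repeat(j - i, c)
            for d in np.unique(d_all):
                k = int((d_all == d).sum())
                # draw k distinct positions along the diagonal
                pos = rng.choice(n - d, size=min(k, n - d), replace=False)
                if k > n - d:  # more contacts than slots: keep multiplicity
                    extra = rng.choice(n - d, size=k - (n - d), replace=True)
                    pos = np.concatenate([pos, extra])
                new_i.append(pos)
                new_j.append(pos + d)
            if new_i:
                ii = np.concatenate(new_i)
                jj = np.concatenate(new_j)
                out[chrom] = (ii, jj, np.ones(len(ii), dtype=np.int64))
    elif mode in ("marginal+scaling", "mss"):
        from . import null_models

        pc = pc_curve(cmap, mode="single_cell")
        for chrom in cmap.chromosomes:
            n = cmap.chrom_bins[chrom]
            i, j, c = cmap.triplets(chrom)
            n_c = int(c.sum())
            if n_c == 0:
                continue
            marg = np.zeros(n)
            np.add.at(marg, i, c)
            np.add.at(marg, j, c)
            pcb = pc.at_bins(cmap.binsize)
            pcb = np.pad(pcb, (0, max(0, n - len(pcb))))[:n]
            ii, jj = null_models.resample_conditioned_on_marginals(
                marg, pcb, n_c, rng=rng
            )
            out[chrom] = (ii, jj, np.ones(len(ii), dtype=np.int64))
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    meta = dict(cmap.metadata)
    meta["shuffled"] = mode
    return SparseContactMap(cmap.binsize, cmap.chrom_bins, out, metadata=meta)


def write_coverage_bedgraph(cmap: SparseContactMap, path) -> None:
    """Per-bin contact coverage as bedGraph (chrom, start, end, count)."""
    with open(path, "w") as fh:
        for chrom in cmap.chromosomes:
            n = cmap.chrom_bins[chrom]
            marg = np.zeros(n, dtype=np.int64)
            i, j, c = cmap.triplets(chrom)
            np.add.at(marg, i, c)
            np.add.at(marg, j, c)
            for b in range(n):
                fh.write(
                    f"{chrom}\t{b * cmap.binsize}\t{(b + 1) * cmap.binsize}\t{marg[b]}\n"
                )


def balance_ice(
    cmap: SparseContactMap,
    chrom: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> dict[str, np.ndarray]:
    """Iterative correction: per-bin weights equalizing marginals.

    Returns ``{chrom: weights}`` with NaN for empty (masked) bins.  The
    balanced matrix is ``w_i w_j A_ij`` with unit mean marginal over
    non-empty bins.  Raises on non-convergence.
    """
    chroms = [chrom] if chrom else cmap.chromosomes
    weights: dict[str, np.ndarray] = {}
    for ch in chroms:
        a = cmap.to_dense(ch)
        n = a.shape[0]
        mask = a.sum(axis=1) > 0
        w = np.ones(n)
        w[~mask] = 0.0
        resid = np.inf
        for _ in range(max_iter):
            b = (w[:, None] * a) * w[None, :]
            marg = b.sum(axis=1)
            mean = marg[mask].mean()
            resid = np.abs(marg[mask] / mean - 1).max() if mask.any() else 0.0
            if resid < tol:
                break
            upd = np.ones(n)
            upd[mask] = marg[mask] / mean
            w = w / upd
        else:
            raise RuntimeError(
                f"ICE did not converge on {ch}: residual {resid:.3e} after {max_iter} iters"
            )
        w_out = w.astype(float)
        w_out[~mask] = np.nan
        weights[ch] = w_out
    return weights
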