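"""Genome segmentations into TADs and inter-TADs.

A :class:`Segmentation` is an ordered, non-overlapping list of segments
``[start_bin, end_bin)`` covering one chromosome, each labeled ``TAD``
or ``interTAD``.  TAD boundaries are represented as *edges* — bin-grid
positions in ``0..N`` where a TAD starts or ends — so that two adjacent
TADs share one boundary and offset matching is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Segmentation", "compare_segmentations", "match_boundaries"]

TAD = "TAD"
INTER = "interTAD"


@dataclass
class Segmentation:
    """Ordered TAD/inter-TAD segments on one chromosome."""

    segments: list[tuple[int, int, str]]
    n_bins: int
    gamma: float | None = None
    binsize: int | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        pos = 0
        for start, end, label in segs:
            if start != pos or end <= start:
                raise ValueError("segments must tile [0, n_bins) without gaps")
            if label not in (TAD, INTER):
                raise ValueError(f"bad label {label!r}")
            pos = end
        if pos != self.n_bins:
            raise ValueError("segments must cover all bins")
        self.segments = segs

    @property
    def tads(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.segments if lab == TAD]

    @property
    def n_tads(self) -> int:
        return len(self.tads)

    def tad_sizes(self) -> np.ndarray:
        return np.array([e - s for s, e in self.tads], dtype=int)

    def median_tad_size(self) -> float:
        sizes = self.tad_sizes()
        return float(np.median(sizes)) if len(sizes) else 0.0

    def coverage(self) -> float:
        """Fraction of bins inside TADs."""
        return float(self.tad_sizes().sum()) / self.n_bins if self.n_bins else 0.0

    def boundary_edges(self) -> np.ndarray:
        """Sorted unique edges where a TAD starts or ends (0..N)."""
        edges = set()
        for s, e in self.tads:
            edges.add(s)
            edges.add(e)
        return np.array(sorted(edges), dtype=int)

    def interior_tad_bins(self) -> np.ndarray:
        """Bins strictly inside TADs, excluding each TAD's edge bins."""
        out = []
        for s, e in self.tads:
            out.extend(range(s + 1, e - 1))
        return np.array(sorted(out), dtype=int)

    def labels_per_bin(self) -> np.ndarray:
        lab = np.zeros(self.n_bins, dtype=int)
        for s, e in self.tads:
            lab[s:e] = 1
        return lab

    def to_bed(self, path, chrom_offset_bp: int = 0) -> None:
        if self.binsize is None:
            raise ValueError("binsize required for BED output")
        with open(path, "w") as fh:
            for s, e, lab in self.segments:
                fh.write(
                    f"{self.chrom}\t{chrom_offset_bp + s * self.binsize}"
                    f"\t{chrom_offset_bp + e * self.binsize}\t{lab}\n"
                )

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        gamma: float | None = None,
        binsize: int | None = None,
        chrom: str = "chr1",
    ) -> "Segmentation":
        """Build from a per-bin 0/1 (interTAD/TAD) label vector."""
        labels = np.asarray(labels)
        segs: list[tuple[int, int, str]] = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                segs.append((start, i, TAD if labels[start] else INTER))
                start = i
        return cls(segs, len(labels), gamma=gamma, binsize=binsize, chrom=chrom)


def match_boundaries(
    edges_a: np.ndarray, edges_b: np.ndarray, offset: int = 1
) -> np.ndarray:
    """Boolean mask over ``edges_a``: has a match in ``edges_b`` within offset."""
    a = np.asarray(edges_a)
    b = np.asarray(edges_b)
    if len(b) == 0:
        return np.zeros(len(a), dtype=bool)
    idx = np.searchsorted(b, a)
    dist = np.full(len(a), np.iinfo(np.int64).max, dtype=np.int64)
    right = idx < len(b)
    dist[right] = np.abs(b[idx[right]] - a[right])
    left = idx > 0
    dist[left] = np.minimum(dist[left], np.abs(a[left] - b[idx[left] - 1]))
    return dist <= offset


def compare_segmentations(
    a: Segmentation, b: Segmentation, offset: int = 1
) -> dict[str, float]:
    """Shared-boundary percentage (relative to A) and TAD-bin Jaccard.

    The shared percentage fixes segmentation A and asks what fraction
    of its TAD boundaries has a B boundary within ``offset`` bins
    (asymmetric by construction).  The Jaccard index is computed over
    interior TAD bins (TAD bins excluding the two edge bins of each
    TAD) and is symmetric.
    """
    if a.n_bins != b.n_bins:
        raise ValueError("segmentations must cover the same bins")
    ea, eb = a.boundary_edges(), b.boundary_edges()
    if len(ea) == 0:
        shared = 0.0
    else:
        shared = 100.0 * match_boundaries(ea, eb, offset).sum() / len(ea)
    ia = set(a.interior_tad_bins().tolist())
    ib = set(b.interior_tad_bins().tolist())
    union = ia | ib
    jac = len(ia & ib) / len(union) if union else 1.0
    return {"shared_boundary_pct": float(shared), "jaccard_tad_bins": float(jac)}
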