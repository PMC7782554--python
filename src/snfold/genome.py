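"""Genome and restriction-fragment primitives.

A genome is an ordered set of chromosomes with per-chromosome copy
numbers (ploidy); BG3-like male cell lines carry autosomes twice and the
X once.  Restriction digestion with a short motif (DpnII: GATC) produces
a :class:`RestrictionMap`, a partition of each chromosome into
restriction fragments — the atomic unit of contact annotation.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "RestrictionMap",
    "make_restriction_map",
    "read_fasta",
    "write_fragments_bed",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with lengths (bp) and copy numbers.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; lengths in bp, > 0.
    ploidy
        Map ``name -> copy number``.  Missing names default to 2
        (autosome in a diploid line).
    """

    chromosomes: tuple[tuple[str, int], ...]
    ploidy: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, name: str) -> int:
        for n, ln in self.chromosomes:
            if n == name:
                return ln
        raise KeyError(name)

    def copy_number(self, name: str) -> int:
        return int(self.ploidy.get(name, 2))


class RestrictionMap:
    """Sorted cut positions and derived fragments per chromosome.

    Fragments partition each chromosome ``[0, L)`` without gaps: the
    intervals between consecutive cuts plus the two chromosome ends.
    Fragment ids are 0-based and chromosome-local.
    """

    def __init__(self, cuts: Mapping[str, Sequence[int]], lengths: Mapping[str, int]):
        self._cuts: dict[str, np.ndarray] = {}
        self._edges: dict[str, np.ndarray] = {}
        self.lengths: dict[str, int] = {}
        for chrom, length in lengths.items():
            length = int(length)
            c = np.asarray(sorted(set(int(x) for x in cuts.get(chrom, ()))), dtype=np.int64)
            c = c[(c > 0) & (c < length)]
            if np.any(np.diff(c) <= 0):
                raise ValueError("cut positions must be strictly increasing")
            self._cuts[chrom] = c
            # fragment boundaries: 0, cuts..., length
            self._edges[chrom] = np.concatenate(([0], c, [length]))
            self.lengths[chrom] = length

    @property
    def chromosomes(self) -> list[str]:
        return list(self._edges)

    def cuts(self, chrom: str) -> np.ndarray:
        return self._cuts[chrom]

    def fragment_edges(self, chrom: str) -> np.ndarray:
        """Boundaries of the fragment partition, ``[0, c1, ..., L]``."""
        return self._edges[chrom]

    def n_fragments(self, chrom: str) -> int:
        return len(self._edges[chrom]) - 1

    def fragments(self, chrom: str) -> list[tuple[int, int]]:
        e = self._edges[chrom]
        return [(int(e[i]), int(e[i + 1])) for i in range(len(e) - 1)]

    def assign_fragment(self, chrom: str, pos: int) -> int:
        """Fragment id whose half-open interval contains ``pos``."""
        if chrom not in self._edges:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.lengths[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside [0, {length}) on {chrom}")
        e = self._edges[chrom]
        # rightmost edge <= pos
        return int(np.searchsorted(e, pos, side="right") - 1)

    def fragment_midpoint(self, chrom: str, frag: int) -> int:
        e = self._edges[chrom]
        return int((e[frag] + e[frag + 1]) // 2)

    def nearest_cut_distance(self, chrom: str, pos: int) -> int:
        """Distance from ``pos`` to the closest cut site.

        Chromosome ends (0 and L) count as sites: a ligated end at the
        very edge of the assembly is indistinguishable from a cut.
        Ties are broken leftward (irrelevant for the distance itself).
        """
        e = self._edges[chrom]
        i = bisect.bisect_left(e, pos)
        best = np.inf
        if i < len(e):
            best = min(best, abs(int(e[i]) - pos))
        if i > 0:
            best = min(best, abs(pos - int(e[i - 1])))
        return int(best)


def make_restriction_map(
    sequences: Mapping[str, str], motif: str = "GATC"
) -> RestrictionMap:
    """In-silico digestion: cut at every motif occurrence start.

    Blunt model: the cut coordinate is the motif start; restriction
    overhang chemistry is ignored since downstream annotation only uses
    positions to within a ~10 bp tolerance.  Overlapping occurrences
    all count.  An empty sequence yields an empty map (no fragments)
    for that chromosome.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    cuts: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in sequences.items():
        seq = seq.upper()
        if not seq:
            continue
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence for {chrom!r} contains invalid symbols {bad}")
        positions = []
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            positions.append(i)
            start = i + 1  # allow overlapping occurrences
        cuts[chrom] = positions
        lengths[chrom] = len(seq)
    return RestrictionMap(cuts, lengths)


def read_fasta(path) -> dict[str, str]:
    """Read a (plain-text) FASTA into ``{name: sequence}``."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fragments_bed(rmap: RestrictionMap, path) -> None:
    """Write the fragment partition as BED: chrom, start, end, fragment_id."""
    with open(path, "w") as fh:
        for chrom in rmap.chromosomes:
            for fid, (start, end) in enumerate(rmap.fragments(chrom)):
                fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")
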