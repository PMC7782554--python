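"""Synthetic genomes, architectures, contact maps, and chimeric reads.

Every downstream stage of the pipeline can be exercised without
external data: this module generates (i) random genome sequences and
their restriction maps, (ii) ground-truth chromatin architectures —
planted TAD partitions, A/B compartment labels, per-bin stickiness and
a power-law contact-probability decay, (iii) sparse single-cell contact
maps sampled from those architectures, and (iv) chimeric read sets
containing true ligation junctions, template-switch artifacts, and
amplification duplicates, with truth labels.

Defaults emulate the study conditions of fly-scale single-nucleus
Hi-C: 10-kb bins, TADs with a median size of ~9 bins (~90 kb), a
contact-probability decay P_c(s) ∝ s^−1.5, heterogeneous bin
stickiness, and 10³–10⁵ contacts per cell.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import GenomeSpec, RestrictionMap, make_restriction_map
from .maps import SparseContactMap
from . import null_models

__all__ = [
    "GroundTruthArchitecture",
    "SimulatedRead",
    "SimulatedReadSet",
    "random_genome",
    "make_architecture",
    "sample_cell_contacts",
    "simulate_chimeric_reads",
]


@dataclass
class GroundTruthArchitecture:
    """Planted chromatin architecture on one chromosome of binned DNA.

    ``boundaries`` are the internal TAD-partition edges (bin-grid
    positions, excluding 0 and n_bins); ``compartment`` holds 'A'/'B'
    per bin; ``stickiness`` the positive per-bin affinity k_i;
    ``decay_exponent``/``decay_scale`` define P_c(s) = scale·s^−exp;
    ``enrichment`` (>1) multiplies intra-TAD link probabilities.
    """

    n_bins: int
    binsize: int
    boundaries: np.ndarray
    compartment: np.ndarray
    stickiness: np.ndarray
    decay_exponent: float
    decay_scale: float = 1.0
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any((b <= 0) | (b >= self.n_bins)):
            raise ValueError("boundaries must be internal edges")
        if len(self.compartment) != self.n_bins:
            raise ValueError("compartment labels must cover all bins")
        if np.any(np.asarray(self.stickiness) <= 0):
            raise ValueError("stickiness must be positive")
        self.boundaries = b

    @property
    def tad_edges(self) -> np.ndarray:
        """All partition edges including 0 and n_bins."""
        return np.concatenate(([0], self.boundaries, [self.n_bins]))

    def tad_sizes(self) -> np.ndarray:
        return np.diff(self.tad_edges)

    def tad_index(self) -> np.ndarray:
        """Per-bin TAD index."""
        return np.searchsorted(self.boundaries, np.arange(self.n_bins), side="right")

    def pc_by_bin(self, n: int | None = None) -> np.ndarray:
        """P_c at separations 0..n−1 bins (index 0 set to 0)."""
        n = n or self.n_bins
        s = np.arange(n, dtype=float)
        pc = np.zeros(n)
        pc[1:] = self.decay_scale * s[1:] ** (-self.decay_exponent)
        return pc


def random_genome(
    chromosomes: Sequence[tuple[str, int]] = (("chr2", 200_000), ("chrX", 100_000)),
    ploidy: dict | None = None,
    gc: float = 0.42,
    seed: int | None = None,
) -> tuple[GenomeSpec, dict[str, str]]:
    """Random genome sequences with fly-like GC content.

    Returns the :class:`GenomeSpec` (X haploid by default, autosomes
    diploid) and the per-chromosome sequences.
    """
    rng = np.random.default_rng(seed)
    if ploidy is None:
        ploidy = {n: (1 if n.lower().endswith("x") else 2) for n, _ in chromosomes}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for name, length in chromosomes:
        seqs[name] = "".join(
            np.array(list("ACGT"))[rng.choice(4, size=length, p=p)]
        )
    return GenomeSpec(tuple(chromosomes), ploidy), seqs


def make_architecture(
    n_bins: int,
    n_tads: int | None = None,
    seed: int | None = None,
    stickiness_model: str = "lognormal",
    decay_exponent: float = 1.5,
    binsize: int = 10_000,
    median_tad_bins: int = 9,
    enrichment: float = 8.0,
    compartment_block_bins: int = 30,
    stickiness_sigma: float = 0.35,
) -> GroundTruthArchitecture:
    """Plant a TAD partition, compartments, and stickiness on n_bins.

    TAD sizes are drawn log-normally around ``median_tad_bins`` (default
    9 bins = 90 kb at 10-kb resolution) and rescaled to tile the
    chromosome exactly with ``n_tads`` domains; ``n_tads`` defaults to
    ``n_bins // median_tad_bins``.  ``stickiness_model`` is 'uniform'
    or 'lognormal' (heterogeneous visibility).  Compartment labels
    alternate A/B in blocks of roughly ``compartment_block_bins``.
    """
    if n_tads is None:
        n_tads = max(1, n_bins // median_tad_bins)
    if n_tads > n_bins // 4:
        raise ValueError("n_tads too large: need >= 4 bins per TAD on average")
    rng = np.random.default_rng(seed)
    # log-normal sizes with median ~ median_tad_bins, min 4 bins
    raw = np.exp(rng.normal(np.log(median_tad_bins), 0.35, size=n_tads))
    sizes = np.maximum(4, np.round(raw * n_bins / raw.sum()).astype(int))
    # fix rounding drift by adjusting the largest domains
    while sizes.sum() != n_bins:
        k = int(np.argmax(sizes)) if sizes.sum() > n_bins else int(np.argmin(sizes))
        sizes[k] += np.sign(n_bins - sizes.sum())
    boundaries = np.cumsum(sizes)[:-1]

    if stickiness_model == "uniform":
        k = np.ones(n_bins)
    elif stickiness_model == "lognormal":
        k = np.exp(rng.normal(0.0, stickiness_sigma, size=n_bins))
    else:
        raise ValueError(f"unknown stickiness model {stickiness_model!r}")

    comp = np.empty(n_bins, dtype="<U1")
    pos, label = 0, "A"
    while pos < n_bins:
        block = max(5, int(rng.normal(compartment_block_bins, compartment_block_bins / 4)))
        comp[pos : pos + block] = label
        label = "B" if label == "A" else "A"
        pos += block

    return GroundTruthArchitecture(
        n_bins=n_bins,
        binsize=binsize,
        boundaries=boundaries,
        compartment=comp,
        stickiness=k,
        decay_exponent=decay_exponent,
        enrichment=enrichment,
    )


def contact_rates(arch: GroundTruthArchitecture, n_contacts: int) -> np.ndarray:
    """Expected bin-pair contact counts: MSS weights × intra-TAD enrichment.

    A 10-kb bin aggregates dozens of restriction fragments, so the
    bin-level contact count of a pair is not 0/1; rates are normalized
    so the expected total over i<j equals ``n_contacts`` and need not
    stay below 1.
    """
    base = null_models.mss_probabilities(
        arch.stickiness, arch.pc_by_bin(), min(n_contacts, 1)
    ).p
    tad = arch.tad_index()
    same = tad[:, None] == tad[None, :]
    w = np.where(same, arch.enrichment, 1.0) * base
    np.fill_diagonal(w, 0.0)
    tot = np.triu(w, 1).sum()
    if tot == 0:
        return w
    return w * (n_contacts / tot)


def sample_cell_contacts(
    arch: GroundTruthArchitecture,
    n_contacts: int,
    seed: int | None = None,
    chrom: str = "chr1",
) -> SparseContactMap:
    """Draw one sparse single-cell map from the planted architecture.

    Contact counts per bin pair are independent Poisson draws with
    rates proportional to k_i·k_j·P_c(|i−j|), multiplied by the
    intra-TAD enrichment factor, normalized so the expected total
    contact count equals ``n_contacts`` (bin-level counts aggregate
    many restriction fragments, so multiplicities > 1 are real).  With
    enrichment 1 and uniform stickiness the per-pair rates reduce to
    the MS null model's probabilities.  The realized triplets are
    distinct (i, j) pairs with i < j and counts >= 1; the diagonal is
    absent by construction.
    """
    if n_contacts < 0:
        raise ValueError("n_contacts must be >= 0")
    n = arch.n_bins
    if n_contacts > 50 * n * (n - 1) / 2:
        raise ValueError("n_contacts exceeds the plausible bin-pair capacity")
    if n_contacts == 0:
        return SparseContactMap(
            arch.binsize, {chrom: n}, metadata={"cell_id": f"sim-{seed}"}
        )
    rng = np.random.default_rng(seed)
    w = contact_rates(arch, n_contacts)
    iu, ju = np.triu_indices(n, 1)
    counts = rng.poisson(w[iu, ju])
    hit = counts > 0
    return SparseContactMap(
        arch.binsize,
        {chrom: n},
        {chrom: (iu[hit], ju[hit], counts[hit].astype(np.int64))},
        metadata={"cell_id": f"sim-{seed}", "diagonals_removed": 0},
    )


# -- chimeric reads ---------------------------------------------------------


@dataclass
class SimulatedRead:
    """One (possibly chimeric) read with mapped parts and truth label.

    ``parts`` are ordered by position in the read; each part is
    ``(chrom, start, end, strand, mapq)`` with 0-based half-open
    genomic coordinates.  ``truth`` ∈ {'P', 'J', 'H'};
    ``dup_group`` identifies amplification-duplicate families.
    """

    read_id: str
    parts: list[tuple[str, int, int, str, int]]
    truth: str
    dup_group: int


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def write_tsv(self, path) -> None:
        """SAM-like TSV: read_id, part_index, chrom, start, end, strand,
        mapq, truth, dup_group."""
        with open(path, "w") as fh:
            fh.write("read_id\tpart\tchrom\tstart\tend\tstrand\tmapq\ttruth\tdup_group\n")
            for r in self.reads:
                for k, (chrom, s, e, st, q) in enumerate(r.parts):
                    fh.write(
                        f"{r.read_id}\t{k}\t{chrom}\t{s}\t{e}\t{st}\t{q}\t{r.truth}\t{r.dup_group}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "SimulatedReadSet":
        by_id: dict[str, SimulatedRead] = {}
        order: list[str] = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                rid, k, chrom, s, e, st, q, truth, dg = line.rstrip("\n").split("\t")
                if rid not in by_id:
                    by_id[rid] = SimulatedRead(rid, [], truth, int(dg))
                    order.append(rid)
                by_id[rid].parts.append((chrom, int(s), int(e), st, int(q)))
        return cls([by_id[r] for r in order])


def _part_for_ligated_end(
    rng: np.random.Generator,
    chrom: str,
    frag: tuple[int, int],
    side: str,
    which_edge: int,
    max_len: int = 150,
    min_len: int = 20,
) -> tuple[str, int, int, str, int]:
    """Chimeric part inside ``frag`` whose ligated end sits at a fragment edge.

    ``side`` is 'left' (ligated end = read-3' end of the part) or
    'right' (ligated end = read-5' end); ``which_edge`` 0/1 selects the
    fragment's start/end coordinate as the ligation point.  Strand is
    chosen so the read-orientation end maps to that genomic edge.
    """
    s, e = frag
    length = int(rng.integers(min_len, max(min_len + 1, min(max_len, e - s))))
    edge = s if which_edge == 0 else e
    if side == "left":
        # read-3' end at `edge`: '+' if edge is the right genomic end
        if which_edge == 1:
            return (chrom, max(s, edge - length), edge, "+", 60)
        return (chrom, edge, min(e, edge + length), "-", 60)
    else:
        # read-5' end at `edge`: '+' if edge is the left genomic end
        if which_edge == 0:
            return (chrom, edge, min(e, edge + length), "+", 60)
        return (chrom, max(s, edge - length), edge, "-", 60)


def simulate_chimeric_reads(
    contacts: Sequence[tuple[str, int, str, int]],
    restriction_map: RestrictionMap,
    switch_rate: float = 0.1,
    dup_rate: float = 0.2,
    seed: int | None = None,
    tolerance: int = 10,
    p_read_rate: float = 0.1,
) -> SimulatedReadSet:
    """Simulate the read evidence for a list of fragment contacts.

    ``contacts`` are ``(chrom1, frag_id1, chrom2, frag_id2)`` tuples.
    Each contact yields one read: with probability ``switch_rate`` a
    template-switch chimera (H) whose junction ends are placed at least
    ``tolerance + 1`` bp from every restriction site (switches landing
    nearer are undetectable by construction and are not generated);
    otherwise a true junction read (J) whose ligated ends sit exactly
    at cut positions.  ``p_read_rate`` adds plain uniquely-mapped P
    reads carrying no junction.  With probability ``dup_rate`` a read
    gains an amplification duplicate: same fragment pair, resheared
    extents, shared ``dup_group``.
    """
    for r in (switch_rate, dup_rate, p_read_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    counter = 0

    def frag_interval(chrom: str, fid: int) -> tuple[int, int]:
        if chrom not in restriction_map.chromosomes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= fid < restriction_map.n_fragments(chrom):
            raise ValueError(f"unknown fragment {fid} on {chrom}")
        edges = restriction_map.fragment_edges(chrom)
        return int(edges[fid]), int(edges[fid + 1])

    def make_J(chrom1, f1, chrom2, f2) -> list:
        # ligated end of the left part at one cut-edge of frag1, right
        # part starting at a cut-edge of frag2
        e1 = int(rng.integers(2))
        e2 = int(rng.integers(2))
        left = _part_for_ligated_end(rng, chrom1, frag_interval(chrom1, f1), "left", e1)
        right = _part_for_ligated_end(rng, chrom2, frag_interval(chrom2, f2), "right", e2)
        return [left, right]

    def off_site_position(chrom, frag) -> int | None:
        s, e = frag
        lo, hi = s + tolerance + 1, e - tolerance - 1
        if hi <= lo:
            return None
        return int(rng.integers(lo, hi))

    def make_H(chrom1, f1, chrom2, f2) -> list | None:
        # both junction ends strictly interior to their fragments,
        # >= tolerance+1 bp from every cut site
        i1, i2 = frag_interval(chrom1, f1), frag_interval(chrom2, f2)
        p1 = off_site_position(chrom1, i1)
        p2 = off_site_position(chrom2, i2)
        if p1 is None or p2 is None:
            return None
        len1 = int(rng.integers(20, 150))
        len2 = int(rng.integers(20, 150))
        left = (chrom1, max(i1[0], p1 - len1), p1, "+", 60)
        right = (chrom2, p2, min(i2[1], p2 + len2), "+", 60)
        return [left, right]

    for chrom1, f1, chrom2, f2 in contacts:
        counter += 1
        dup_group = counter
        if rng.random() < switch_rate:
            parts = make_H(chrom1, f1, chrom2, f2)
            if parts is None:  # fragment too short to host an off-site break
                parts = make_J(chrom1, f1, chrom2, f2)
                truth = "J"
            else:
                truth = "H"
        else:
            parts = make_J(chrom1, f1, chrom2, f2)
            truth = "J"
        reads.append(SimulatedRead(f"read{counter:07d}", parts, truth, dup_group))
        if truth == "J" and rng.random() < dup_rate:
            counter += 1
            reads.append(
                SimulatedRead(
                    f"read{counter:07d}",
                    make_J(chrom1, f1, chrom2, f2),
                    "J",
                    dup_group,
                )
            )
        if rng.random() < p_read_rate:
            counter += 1
            s, e = frag_interval(chrom1, f1)
            start = int(rng.integers(s, e))
            reads.append(
                SimulatedRead(
                    f"read{counter:07d}",
                    [(chrom1, start, min(e, start + 100), "+", 60)],
                    "P",
                    counter,
                )
            )
    return SimulatedReadSet(reads)
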