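"""LBD contig recovery (assembly surrogate) and k-mer read mapping.

Real de novo assembly is out of scope; what the pipeline needs from it is
its *selectivity*: only populations whose DNA actually banded in the
12C LBD pool at sufficient depth yield reference sequences. ``recover_contigs``
therefore thresholds each population's pooled LBD depth and, for recoverable
genomes, emits the genome cut into a few random contiguous fragments
("contigs"), mimicking partial recovery. This surrogate is the one stage
that consults ground truth (it stands in for the assembler, which would see
the reads themselves); every downstream call is truth-blind.

Read mapping is alignment-free: a read is assigned to the contig sharing
the most canonical k-mers with it (exact matching, default k=21; ties break
to the lexicographically smallest contig id; zero shared k-mers = unmapped).
Per contig and library this yields mapped read counts, mean depth (aligned
bases / contig length, with each read placed at its best seed diagonal) and
breadth (fraction of positions covered >= 1x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _accel, _codec
from .community import Genome, hash_stable
from .sequencing import ReadLibrary


class DesignViolationError(ValueError):
    """A stage was fed libraries the study design forbids."""


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    source_pop_id: str
    start: int  # interval on the source genome, 0-based half-open
    end: int

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return _codec.gc_fraction(self.sequence)


@dataclass
class ContigSet:
    contigs: list[Contig]
    provenance: list[str] = field(default_factory=list)  # library ids used
    min_contig_length: int = 5_000

    def __post_init__(self) -> None:
        for c in self.contigs:
            if len(c) < self.min_contig_length:
                raise ValueError(
                    f"contig {c.contig_id} ({len(c)} bp) below minimum "
                    f"{self.min_contig_length} bp"
                )
        self.contigs = sorted(self.contigs, key=lambda c: c.contig_id)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    def index(self, k: int) -> "KmerIndex":
        cached = getattr(self, "_index", None)
        if cached is None or cached.k != k:
            cached = KmerIndex.build(self, k)
            self._index = cached  # type: ignore[attr-defined]
        return cached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [c.contig_id for c in self.contigs],
                "length": [len(c) for c in self.contigs],
                "gc": [round(c.gc, 6) for c in self.contigs],
                "source_pop_id": [c.source_pop_id for c in self.contigs],
                "start": [c.start for c in self.contigs],
                "end": [c.end for c in self.contigs],
            }
        )


def recover_contigs(
    lbd_libraries: list[ReadLibrary],
    genomes: dict[str, Genome],
    min_depth: float = 5.0,
    min_contig_length: int = 5_000,
    max_fragments: int = 8,
    min_fragments: int = 2,
    seed: int = 0,
) -> ContigSet:
    """Assembly surrogate: recover fragmented genomes from 12C LBD libraries.

    A population is recoverable iff its pooled mean depth across the supplied
    libraries (total bases from that population / genome length) reaches
    ``min_depth``. Recoverable genomes are cut at uniform random points into
    2-8 contiguous fragments, each at least ``min_contig_length`` bp.
    Fragmentation is seeded per population, so the output is invariant to
    library order.
    """
    for lib in lbd_libraries:
        if lib.pool != "LBD" or lib.treatment != "12C":
            raise DesignViolationError(
                f"recover_contigs requires 12C LBD libraries; got "
                f"{lib.library_id} (pool={lib.pool}, treatment={lib.treatment})"
            )

    # pooled depth per population across all supplied libraries
    bases: dict[str, float] = {}
    for lib in lbd_libraries:
        for pid, n in lib.truth_counts().items():
            if n:
                bases[pid] = bases.get(pid, 0.0) + float(n) * lib.read_length

    contigs: list[Contig] = []
    serial = 0
    for pid in sorted(genomes):
        genome = genomes[pid]
        depth = bases.get(pid, 0.0) / len(genome)
        if depth < min_depth:
            continue
        rng = np.random.default_rng((seed * 1_000_003 + hash_stable(pid)) % 2**32)
        length = len(genome)
        cap = length // min_contig_length
        if cap < min_fragments:
            n_frag = max(1, cap)
        else:
            n_frag = int(rng.integers(min_fragments, min(max_fragments, cap) + 1))
        excess = length - n_frag * min_contig_length
        if n_frag > 1:
            cuts = np.sort(rng.integers(0, excess + 1, size=n_frag - 1))
            parts = np.diff(np.concatenate(([0], cuts, [excess])))
        else:
            parts = np.array([excess])
        lengths = parts + min_contig_length
        start = 0
        for ln in lengths:
            end = start + int(ln)
            serial += 1
            contigs.append(
                Contig(
                    contig_id=f"c{serial:05d}",
                    sequence=genome.sequence[start:end],
                    source_pop_id=pid,
                    start=start,
                    end=end,
                )
            )
            start = end
        assert start == length

    return ContigSet(
        contigs=contigs,
        provenance=sorted(lib.library_id for lib in lbd_libraries),
        min_contig_length=min_contig_length,
    )


# ---------------------------------------------------------------------------
# k-mer index and mapping


@dataclass
class KmerIndex:
    k: int
    contig_ids: list[str]  # lexicographically sorted
    lengths: np.ndarray  # (n_contigs,)
    kmers: np.ndarray  # sorted uint64 canonical k-mers (unique)
    contig_of: np.ndarray  # (n_kmers,) int32
    pos_of: np.ndarray  # (n_kmers,) int32 first occurrence position
    table_keys: np.ndarray = None  # open-addressing hash table (numba path)
    table_vals: np.ndarray = None

    @classmethod
    def build(cls, contigs: ContigSet, k: int) -> "KmerIndex":
        ids = [c.contig_id for c in contigs]  # ContigSet is sorted already
        lengths = np.array([len(c) for c in contigs], dtype=np.int64)
        all_kmers, all_contig, all_pos = [], [], []
        for ci, c in enumerate(contigs):
            codes = _codec.encode(c.sequence)
            if len(codes) < k:
                continue
            km = _codec.canonical_kmers(codes, k)
            all_kmers.append(km)
            all_contig.append(np.full(len(km), ci, dtype=np.int32))
            all_pos.append(np.arange(len(km), dtype=np.int32))
        if all_kmers:
            km = np.concatenate(all_kmers)
            ct = np.concatenate(all_contig)
            ps = np.concatenate(all_pos)
            # stable sort by k-mer; a k-mer shared by several contigs (rare
            # random collision) is credited to its first occurrence only
            order = np.argsort(km, kind="stable")
            km, ct, ps = km[order], ct[order], ps[order]
            keep = np.concatenate(([True], km[1:] != km[:-1]))
            km, ct, ps = km[keep], ct[keep], ps[keep]
        else:
            km = np.empty(0, dtype=np.uint64)
            ct = np.empty(0, dtype=np.int32)
            ps = np.empty(0, dtype=np.int32)
        table_keys, table_vals = _accel.make_table(km, ct, ps)
        return cls(
            k=k,
            contig_ids=ids,
            lengths=lengths,
            kmers=km,
            contig_of=ct,
            pos_of=ps,
            table_keys=table_keys,
            table_vals=table_vals,
        )


@dataclass
class MappingResult:
    """Per-contig mapping statistics for one library."""

    library_id: str
    contig_ids: list[str]
    lengths: np.ndarray
    counts: np.ndarray  # mapped read count per contig
    depth: np.ndarray  # mean depth (aligned bases / length)
    breadth: np.ndarray  # fraction of positions covered >= 1x
    unmapped: int
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": self.contig_ids,
                "library_id": self.library_id,
                "length": self.lengths,
                "mapped_read_count": self.counts,
                "mean_depth": np.round(self.depth, 8),
                "breadth": np.round(self.breadth, 8),
            }
        )

    def per_contig(self, contig_id: str) -> tuple[int, float, float]:
        i = self.contig_ids.index(contig_id)
        return int(self.counts[i]), float(self.depth[i]), float(self.breadth[i])


def map_reads(library: ReadLibrary, contigs: ContigSet, k: int = 21) -> MappingResult:
    """Assign each read to the contig sharing the most canonical k-mers.

    Ties break to the lexicographically smallest contig_id; reads sharing no
    k-mer with any contig are unmapped. An assigned read is placed at the
    diagonal of its first matching k-mer and contributes read_length aligned
    bases (clipped at contig ends) to depth and breadth.
    """
    if k > library.read_length:
        raise ValueError(f"k={k} exceeds read length {library.read_length}")
    index = contigs.index(k)
    nc = len(index.contig_ids)
    n = library.depth
    lengths = index.lengths
    if n == 0 or nc == 0:
        return MappingResult(
            library_id=library.library_id,
            contig_ids=index.contig_ids,
            lengths=lengths,
            counts=np.zeros(nc, dtype=np.int64),
            depth=np.zeros(nc),
            breadth=np.zeros(nc),
            unmapped=n,
            total_reads=n,
        )

    if _accel.HAVE_NUMBA:
        best_contig, _shared, starts, ends = _accel.assign_reads(
            library.reads, k, index.table_keys, index.table_vals, nc, lengths
        )
    else:
        best_contig, _shared, starts, ends = _accel.assign_reads_numpy(
            library.reads, k, index.kmers, index.contig_of, index.pos_of, nc, lengths
        )
    mapped = best_contig >= 0
    c_f = best_contig[mapped]
    counts = np.bincount(c_f, minlength=nc).astype(np.int64)

    aligned = (ends[mapped] - starts[mapped]).astype(np.float64)
    depth = np.zeros(nc)
    np.add.at(depth, c_f, aligned)
    depth /= np.maximum(lengths, 1)

    # breadth via a concatenated coverage difference array
    offsets_c = np.concatenate(([0], np.cumsum(lengths + 1)))
    diff = np.zeros(int(offsets_c[-1]), dtype=np.int32)
    np.add.at(diff, offsets_c[c_f] + starts[mapped], 1)
    np.add.at(diff, offsets_c[c_f] + ends[mapped], -1)
    cov = np.cumsum(diff) > 0
    breadth = np.array(
        [cov[offsets_c[i] : offsets_c[i] + lengths[i]].sum() for i in range(nc)],
        dtype=np.float64,
    ) / np.maximum(lengths, 1)

    return MappingResult(
        library_id=library.library_id,
        contig_ids=index.contig_ids,
        lengths=lengths,
        counts=counts,
        depth=depth,
        breadth=breadth,
        unmapped=int(n - mapped.sum()),
        total_reads=n,
    )


def feature_proportions(
    mapping: MappingResult,
    library: ReadLibrary,
    features: dict[str, list[str]],
) -> pd.Series:
    """Per-feature relative proportion of the library's reads.

    A feature is a group of contigs — the MAG analog (all contigs recovered
    from one population) or a single virus contig. Proportions are
    normalized by the library's *total* read count, so features plus
    non-feature contigs plus unmapped reads sum to 1.
    """
    if library.depth == 0:
        raise ValueError("cannot compute proportions for a zero-depth library")
    count_by_contig = dict(zip(mapping.contig_ids, mapping.counts))
    values = {
        fid: sum(count_by_contig.get(cid, 0) for cid in cids) / library.depth
        for fid, cids in features.items()
    }
    return pd.Series(values, name=mapping.library_id)


def mag_features(contigs: ContigSet, host_pop_ids: list[str]) -> dict[str, list[str]]:
    """MAG-analog grouping: one feature per host population's contigs.

    Uses contig provenance as a stand-in for binning (binning quality is out
    of scope); only populations that yielded contigs appear.
    """
    out: dict[str, list[str]] = {}
    for c in contigs:
        if c.source_pop_id in host_pop_ids:
            out.setdefault(f"MAG:{c.source_pop_id}", []).append(c.contig_id)
    return out


def write_contigs_fasta(contigs: ContigSet, path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} source={c.source_pop_id}:{c.start}-{c.end}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
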