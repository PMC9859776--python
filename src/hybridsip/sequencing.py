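"""Read sampling from pooled gradient DNA.

A replicate library is a multinomial draw of single-end reads over
populations, with per-population probability proportional to pooled DNA
*mass* (not genome copy number — long genomes contribute proportionally more
mass at equal copy number; this conflation is deliberate and documented).
Read start positions are uniform on the linear genome (no wraparound) and
substitution errors are i.i.d. per base. Reads carry their true source
population for tests and reports; the pipeline's calls never read it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from . import _codec
from .community import Genome

logger = logging.getLogger(__name__)


@dataclass
class ReadLibrary:
    """One replicate sequencing library (single-end, fixed read length)."""

    library_id: str
    soil: str
    treatment: str  # "12C" | "13C"
    pool: str  # "LBD" | "HBD"
    replicate: int
    read_length: int
    reads: np.ndarray  # (depth, read_length) uint8 base codes
    truth_pop: np.ndarray  # (depth,) index into truth_pop_ids
    truth_pop_ids: list[str]

    @property
    def depth(self) -> int:
        return int(self.reads.shape[0])

    def read_id(self, i: int) -> str:
        return f"{self.library_id}:r{i:06d}"

    def sequence(self, i: int) -> str:
        return _codec.decode(self.reads[i])

    def iter_reads(self) -> Iterator[tuple[str, str, str]]:
        """Yield (read_id, sequence, truth_pop_id) tuples."""
        for i in range(self.depth):
            yield self.read_id(i), self.sequence(i), self.truth_pop_ids[self.truth_pop[i]]

    def truth_counts(self) -> pd.Series:
        counts = np.bincount(self.truth_pop, minlength=len(self.truth_pop_ids))
        return pd.Series(counts, index=self.truth_pop_ids, name=self.library_id)


def sample_reads(
    pooled_mass: pd.Series,
    genomes: dict[str, Genome],
    depth: int,
    read_length: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
    library_id: str = "lib",
    soil: str = "",
    treatment: str = "",
    pool: str = "",
    replicate: int = 1,
) -> ReadLibrary:
    """Sample a read library from a per-population pooled-mass vector.

    Populations shorter than the read length are excluded (with a warning);
    an all-zero mass vector with positive depth is an error.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    mass = pooled_mass.astype(float).copy()
    for pid in list(mass.index):
        if mass[pid] > 0 and len(genomes[pid]) < read_length:
            logger.warning(
                "population %s genome (%d bp) shorter than read length %d; excluded",
                pid,
                len(genomes[pid]),
                read_length,
            )
            mass[pid] = 0.0

    pop_ids = list(mass.index)
    total = float(mass.sum())
    if depth == 0:
        return ReadLibrary(
            library_id=library_id,
            soil=soil,
            treatment=treatment,
            pool=pool,
            replicate=replicate,
            read_length=read_length,
            reads=np.empty((0, read_length), dtype=np.uint8),
            truth_pop=np.empty(0, dtype=np.int64),
            truth_pop_ids=pop_ids,
        )
    if total <= 0:
        raise ValueError("cannot sample reads: pooled mass vector is all zero")

    probs = (mass / total).to_numpy()
    counts = rng.multinomial(depth, probs)

    reads = np.empty((depth, read_length), dtype=np.uint8)
    truth = np.empty(depth, dtype=np.int64)
    cursor = 0
    for pi, (pid, n) in enumerate(zip(pop_ids, counts)):
        if n == 0:
            continue
        codes = _genome_codes(genomes[pid])
        starts = rng.integers(0, len(codes) - read_length + 1, size=n)
        block = codes[starts[:, None] + np.arange(read_length)[None, :]]
        reads[cursor : cursor + n] = block
        truth[cursor : cursor + n] = pi
        cursor += n

    if error_rate > 0:
        n_err = rng.binomial(depth * read_length, error_rate)
        if n_err > 0:
            flat_pos = rng.choice(depth * read_length, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            flat = reads.reshape(-1)
            flat[flat_pos] = (flat[flat_pos] + shift) % 4

    return ReadLibrary(
        library_id=library_id,
        soil=soil,
        treatment=treatment,
        pool=pool,
        replicate=replicate,
        read_length=read_length,
        reads=reads,
        truth_pop=truth,
        truth_pop_ids=pop_ids,
    )


def _genome_codes(genome: Genome) -> np.ndarray:
    # cached on the genome object; invalidated if the sequence is replaced
    cached = getattr(genome, "_codes", None)
    if cached is None or len(cached) != len(genome):
        cached = _codec.encode(genome.sequence)
        genome._codes = cached  # type: ignore[attr-defined]
    return cached


def write_reads_fasta(library: ReadLibrary, path) -> None:
    """FASTA with the truth tag in the header (for tests/reports only)."""
    with open(path, "w") as fh:
        for read_id, seq, truth in library.iter_reads():
            fh.write(f">{read_id} truth={truth}\n{seq}\n")
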