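"""Readers for persisted run-directory artefacts.

Each pipeline stage writes standard text formats (FASTA, GFF3, TSV, YAML,
JSON); these loaders reconstruct the in-memory objects so any stage can be
re-run from its persisted inputs, and so real (non-synthetic) contigs or
mapping tables can enter the chain mid-way.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _codec
from .community import Cassette, Genome, PopulationSpec, Scenario
from .mapping import Contig, ContigSet, MappingResult
from .sequencing import ReadLibrary

_LIB_ID = re.compile(r"^(?P<soil>[^_]+)_(?P<treatment>1[23]C)_(?P<pool>[LH]BD)_r(?P<rep>\d+)$")


def parse_library_id(library_id: str) -> dict:
    m = _LIB_ID.match(library_id)
    if not m:
        raise ValueError(f"library id {library_id!r} not of form soil_treatment_pool_rN")
    d = m.groupdict()
    d["rep"] = int(d["rep"])
    return d


def load_scenario(run_dir) -> Scenario:
    run_dir = Path(run_dir)
    data = yaml.safe_load((run_dir / "scenario.yaml").read_text())
    populations = [PopulationSpec(**p) for p in data["populations"]]

    sequences: dict[str, str] = {}
    pid = None
    chunks: list[str] = []
    for line in (run_dir / "genomes.fasta").read_text().splitlines():
        if line.startswith(">"):
            if pid is not None:
                sequences[pid] = "".join(chunks)
            pid = line[1:].split("|")[0].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if pid is not None:
        sequences[pid] = "".join(chunks)

    cassettes: dict[str, list[Cassette]] = {}
    gff = run_dir / "cassettes.gff3"
    if gff.exists():
        for line in gff.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, _type, start, end, _score, strand, _phase, attrs = line.split("\t")
            meta = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            cassettes.setdefault(seqid, []).append(
                Cassette(
                    gene_kind=meta["kind"],
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    query_id=meta.get("query", ""),
                )
            )

    genomes = {
        pid: Genome(
            pop_id=pid,
            sequence=seq,
            realized_gc=_codec.gc_fraction(seq),
            cassettes=cassettes.get(pid, []),
        )
        for pid, seq in sequences.items()
    }
    return Scenario(populations=populations, genomes=genomes, replicates=data.get("replicates", 3))


def load_library_fasta(path, library_id: str | None = None) -> ReadLibrary:
    path = Path(path)
    lid = library_id or path.stem
    meta = parse_library_id(lid)
    seqs: list[str] = []
    truth: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            m = re.search(r"truth=(\S+)", line)
            truth.append(m.group(1) if m else "unknown")
        elif line.strip():
            seqs.append(line.strip())
    if len(seqs) != len(truth):
        raise ValueError(f"{path}: malformed read FASTA (multi-line records unsupported)")
    pop_ids = sorted(set(truth)) or ["unknown"]
    pop_index = {p: i for i, p in enumerate(pop_ids)}
    read_length = len(seqs[0]) if seqs else 0
    reads = (
        np.stack([_codec.encode(s) for s in seqs])
        if seqs
        else np.empty((0, read_length), dtype=np.uint8)
    )
    return ReadLibrary(
        library_id=lid,
        soil=meta["soil"],
        treatment=meta["treatment"],
        pool=meta["pool"],
        replicate=meta["rep"],
        read_length=read_length,
        reads=reads,
        truth_pop=np.array([pop_index[t] for t in truth], dtype=np.int64),
        truth_pop_ids=pop_ids,
    )


def load_libraries(run_dir) -> dict[str, ReadLibrary]:
    rdir = Path(run_dir) / "reads"
    out = {}
    for path in sorted(rdir.glob("*.fasta")):
        lib = load_library_fasta(path)
        out[lib.library_id] = lib
    if not out:
        raise FileNotFoundError(f"no read FASTA files under {rdir}")
    return out


def load_contigs(run_dir) -> ContigSet:
    run_dir = Path(run_dir)
    table = pd.read_csv(run_dir / "contigs.tsv", sep="\t")
    seqs: dict[str, str] = {}
    cid = None
    chunks: list[str] = []
    for line in (run_dir / "contigs.fasta").read_text().splitlines():
        if line.startswith(">"):
            if cid is not None:
                seqs[cid] = "".join(chunks)
            cid = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if cid is not None:
        seqs[cid] = "".join(chunks)
    contigs = [
        Contig(
            contig_id=row.contig_id,
            sequence=seqs[row.contig_id],
            source_pop_id=row.source_pop_id,
            start=int(row.start),
            end=int(row.end),
        )
        for row in table.itertuples()
    ]
    min_len = min((len(c) for c in contigs), default=1)
    return ContigSet(contigs=contigs, min_contig_length=min(min_len, 5_000))


def load_mappings(run_dir) -> tuple[dict[str, MappingResult], pd.DataFrame]:
    """Rebuild per-library MappingResults from mapping.tsv + library_stats.tsv."""
    run_dir = Path(run_dir)
    table = pd.read_csv(run_dir / "mapping.tsv", sep="\t")
    stats = pd.read_csv(run_dir / "library_stats.tsv", sep="\t").set_index("library_id")
    out: dict[str, MappingResult] = {}
    for lid, sub in table.groupby("library_id", sort=True):
        sub = sub.sort_values("contig_id")
        out[lid] = MappingResult(
            library_id=lid,
            contig_ids=list(sub["contig_id"]),
            lengths=sub["length"].to_numpy(),
            counts=sub["mapped_read_count"].to_numpy(),
            depth=sub["mean_depth"].to_numpy(dtype=float),
            breadth=sub["breadth"].to_numpy(dtype=float),
            unmapped=int(stats.loc[lid, "unmapped"]),
            total_reads=int(stats.loc[lid, "total_reads"]),
        )
    return out, stats
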