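"""Packaged hallmark-protein fixture set and codon-level back-translation.

The package ships a small FASTA of synthetic, fixed protein sequences that
stand in for a curated database of provirus-derived hallmark genes (major
capsid protein, large terminase, portal, integrase) plus the AOA-specific
type 1 multicopper oxidase (MCO1) auxiliary metabolic gene. Each entry is
annotated with the host guild (AOA, AOB or NOB) its notional provirus came
from; virus-contig screening propagates that annotation into host-guild
predictions. The sequences are random draws from background amino-acid
frequencies — they carry no biological signal and exist only so that
cassette insertion, ORF detection and homology search have a fixed,
reproducible target set.

Back-translation maps a protein onto DNA using, per residue, the sense codon
whose GC content is closest to a requested genome-wide GC target (ties break
to the alphabetically first codon), so inserted cassettes perturb a genome's
GC as little as the code allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from Bio.Data.CodonTable import standard_dna_table

GENE_KINDS = ("capsid", "terminase", "portal", "integrase", "mco1")
#: hallmark kinds that identify a virion-forming virus; integrase alone does
#: not (hosts encode integrases too)
VIRION_KINDS = frozenset({"capsid", "terminase", "portal"})
GUILDS = ("AOA", "AOB", "NOB")

_DATA_FILE = "hallmarks_synthetic.faa"

_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class HallmarkProtein:
    query_id: str
    gene_kind: str
    guild: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@lru_cache(maxsize=1)
def load_hallmarks() -> tuple[HallmarkProtein, ...]:
    """Load the packaged hallmark fixture set (synthetic surrogate DB)."""
    text = resources.files("hybridsip.data").joinpath(_DATA_FILE).read_text()
    entries: list[HallmarkProtein] = []
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                entries.append(_parse_entry(header, "".join(chunks)))
            header, chunks = line[1:], []
        elif line.strip():
            chunks.append(line.strip())
    if header is not None:
        entries.append(_parse_entry(header, "".join(chunks)))
    return tuple(entries)


def _parse_entry(header: str, seq: str) -> HallmarkProtein:
    fields = header.split()
    meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
    return HallmarkProtein(
        query_id=fields[0], gene_kind=meta["kind"], guild=meta["guild"], seq=seq
    )


def hallmarks_by_kind(gene_kind: str, guild: str | None = None) -> list[HallmarkProtein]:
    out = [h for h in load_hallmarks() if h.gene_kind == gene_kind]
    if guild is not None:
        out = [h for h in out if h.guild == guild]
    if not out:
        raise KeyError(f"no hallmark fixtures of kind={gene_kind!r} guild={guild!r}")
    return out


def _codon_gc(codon: str) -> float:
    return (codon.count("G") + codon.count("C")) / 3.0


@lru_cache(maxsize=128)
def _codon_choice(gc_target: float) -> dict[str, str]:
    """Per amino acid, the sense codon with GC closest to gc_target."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return {
        aa: min(codons, key=lambda c: (abs(_codon_gc(c) - gc_target), c))
        for aa, codons in by_aa.items()
    }


def stop_codon(gc_target: float) -> str:
    return min(_STOP_CODONS, key=lambda c: (abs(_codon_gc(c) - gc_target), c))


def backtranslate(protein: str, gc_target: float) -> str:
    """Back-code a protein to DNA with codons matching gc_target; appends a stop.

    Deterministic: depends only on the protein and the GC target, so an
    inserted cassette is an exact nucleotide duplicate wherever it recurs at
    the same GC, and its translation is an exact copy of the query protein.
    """
    table = _codon_choice(round(gc_target, 6))
    try:
        body = "".join(table[aa] for aa in protein)
    except KeyError as exc:  # pragma: no cover - guarded by fixture content
        raise ValueError(f"cannot back-translate residue {exc}") from exc
    return body + stop_codon(gc_target)
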