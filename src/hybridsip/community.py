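"""Synthetic two-soil nitrifier community with known ground truth.

Generates the populations and genomes that a DNA-SIP microcosm study of
ammonia-oxidising archaea (AOA) and their viruses would contain: per soil, a
handful of low-GC (~38 mol%) AOA host populations (most of them autotrophic
and hence 13C-labelled under a 13CO2 headspace), a dominant high-GC
(57-67 mol%) background community that assimilates no CO2-derived carbon,
and viruses whose GC tracks their host's (AOA viruses average ~36.3 mol%).
Hallmark-gene cassettes (capsid, terminase, portal, integrase, MCO1) are
back-coded onto virus — and, for integrase/MCO1, host — genomes so the
downstream homology screen has real targets.

Ground truth (which population a genome belongs to, who is labelled, which
contig carries which cassette) is carried alongside every artefact; the
pipeline's *calls* never consult it, only tests and reports do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _codec
from .hallmarks import (
    GENE_KINDS,
    HallmarkProtein,
    backtranslate,
    hallmarks_by_kind,
)

#: atom fraction 13C of carbon at natural abundance; applies to every
#: population under the 12C treatment and to inactive populations under 13C.
NATURAL_13C = 0.011

SOILS = ("pH4.5", "pH7.5")
TREATMENTS = ("12C", "13C")
GUILD_ENUM = ("AOA_host", "AOB_host", "NOB_host", "background", "virus")

GC_RANGE = (0.2, 0.8)
MIN_GENOME_LENGTH = 5_000
MAX_GENOME_LENGTH = 5_000_000


@dataclass(frozen=True)
class Cassette:
    """A hallmark-gene cassette placed on a genome (0-based, half-open)."""

    gene_kind: str
    start: int
    end: int
    strand: str  # "+" or "-"
    query_id: str

    def __post_init__(self) -> None:
        if self.gene_kind not in GENE_KINDS:
            raise ValueError(f"unknown gene_kind {self.gene_kind!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError("cassette interval must be non-empty and non-negative")


@dataclass
class PopulationSpec:
    """Ground-truth description of one organism or virus population."""

    pop_id: str
    guild: str
    gc_target: float
    genome_length: int
    abundance: dict[str, float]  # soil -> relative abundance
    active: dict[str, bool]  # treatment -> assimilates CO2-derived carbon
    atom13c: float  # atom fraction 13C achieved under 13C treatment if active
    host_id: str | None = None  # viruses only
    temperate: bool | None = None  # viruses only

    def atom_fraction(self, treatment: str) -> float:
        """Achieved 13C atom fraction of this population's DNA under a treatment."""
        if treatment == "13C" and self.active.get(treatment, False):
            return self.atom13c
        return NATURAL_13C

    def is_virus(self) -> bool:
        return self.guild == "virus"


@dataclass
class Genome:
    pop_id: str
    sequence: str
    realized_gc: float
    cassettes: list[Cassette] = field(default_factory=list)
    notes: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def cassette_seq(self, cassette: Cassette) -> str:
        return self.sequence[cassette.start : cassette.end]


@dataclass
class Scenario:
    """A full two-soil study design: populations plus their genomes."""

    populations: list[PopulationSpec]
    genomes: dict[str, Genome]  # pop_id -> genome
    replicates: int = 3

    def population(self, pop_id: str) -> PopulationSpec:
        for p in self.populations:
            if p.pop_id == pop_id:
                return p
        raise KeyError(pop_id)

    def soils(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            for s in p.abundance:
                if s not in seen:
                    seen.append(s)
        return seen

    def validate(self) -> None:
        ids = {p.pop_id for p in self.populations}
        if len(ids) != len(self.populations):
            raise ValueError("duplicate pop_ids")
        for soil in self.soils():
            total = sum(p.abundance.get(soil, 0.0) for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances in soil {soil} sum to {total}, not 1")
        for p in self.populations:
            if p.is_virus():
                if p.host_id not in ids:
                    raise ValueError(f"virus {p.pop_id} references unknown host {p.host_id}")
                genome = self.genomes.get(p.pop_id)
                if genome is not None and p.temperate is not None:
                    has_int = any(c.gene_kind == "integrase" for c in genome.cassettes)
                    if has_int != p.temperate:
                        raise ValueError(
                            f"virus {p.pop_id}: temperate={p.temperate} but "
                            f"integrase cassette {'present' if has_int else 'absent'}"
                        )


# ---------------------------------------------------------------------------
# genome generation


@dataclass(frozen=True)
class CassettePlan:
    """Requested cassette: which hallmark to insert and (optionally) where."""

    gene_kind: str
    query_id: str | None = None  # default: first AOA fixture of that kind
    start: int | None = None  # default: auto-placed
    strand: str | None = None  # default: drawn from the seed


def _resolve_query(plan: CassettePlan) -> HallmarkProtein:
    if plan.query_id is None:
        return hallmarks_by_kind(plan.gene_kind)[0]
    for h in hallmarks_by_kind(plan.gene_kind):
        if h.query_id == plan.query_id:
            return h
    raise KeyError(f"no hallmark fixture {plan.query_id!r} of kind {plan.gene_kind!r}")


def generate_genome(
    length: int,
    gc_target: float,
    cassettes: list[CassettePlan] | None = None,
    seed: int = 0,
    pop_id: str = "genome",
    notes: str = "",
) -> Genome:
    """Generate one genome: cassette inserts on a random background.

    The background (non-cassette) sequence has an exact base composition:
    the G+C count is chosen so the whole genome's realized GC equals
    gc_target as closely as integer counts allow (compensating for the GC
    of back-coded cassettes), and the bases are then randomly permuted.
    Positions are exchangeable and carry no k-mer structure; buoyant-density
    migration only depends on GC, so nothing downstream sees the difference
    from an i.i.d. draw, and the realized-GC tolerance holds at every length.
    """
    if not GC_RANGE[0] <= gc_target <= GC_RANGE[1]:
        raise ValueError(f"gc_target {gc_target} outside [{GC_RANGE[0]}, {GC_RANGE[1]}]")
    if not MIN_GENOME_LENGTH <= length <= MAX_GENOME_LENGTH:
        raise ValueError(f"length {length} outside [{MIN_GENOME_LENGTH}, {MAX_GENOME_LENGTH}]")
    rng = np.random.default_rng(seed)
    plans = list(cassettes or [])

    # materialise cassette nucleotide sequences first
    inserts: list[tuple[CassettePlan, HallmarkProtein, str]] = []
    for plan in plans:
        query = _resolve_query(plan)
        nt = backtranslate(query.seq, gc_target)
        inserts.append((plan, query, nt))

    # place cassettes: honour explicit starts, auto-place the rest left to
    # right with seeded gaps
    placed: list[tuple[int, int, CassettePlan, HallmarkProtein, str]] = []
    cursor = int(rng.integers(0, max(1, length // 10)))
    for plan, query, nt in inserts:
        if plan.start is not None:
            start = plan.start
        else:
            start = cursor + int(rng.integers(200, 1_000))
        end = start + len(nt)
        if end > length:
            raise ValueError(
                f"cassette {query.query_id} ({plan.gene_kind}) does not fit: "
                f"[{start}, {end}) exceeds genome length {length}"
            )
        placed.append((start, end, plan, query, nt))
        cursor = end
    placed.sort(key=lambda t: t[0])
    for (s1, e1, _, q1, _), (s2, _e2, _, q2, _) in zip(placed, placed[1:]):
        if s2 < e1:
            raise ValueError(f"cassettes {q1.query_id} and {q2.query_id} overlap")

    cassette_len = sum(e - s for s, e, *_ in placed)
    cassette_gc = sum(nt.count("G") + nt.count("C") for *_, nt in placed)
    bg_len = length - cassette_len
    n_gc = int(round(gc_target * length - cassette_gc))
    n_gc = min(max(n_gc, 0), bg_len)
    n_g, n_c = n_gc // 2, n_gc - n_gc // 2
    n_at = bg_len - n_gc
    n_a, n_t = n_at // 2, n_at - n_at // 2
    background = np.repeat(
        np.array([0, 1, 2, 3], dtype=np.uint8), [n_a, n_c, n_g, n_t]
    )
    rng.shuffle(background)

    # splice cassettes into the background
    final_cassettes: list[Cassette] = []
    parts: list[str] = []
    bg_pos = 0
    prev_end = 0
    bg_str = _codec.decode(background)
    for start, end, plan, query, nt in placed:
        gap = start - prev_end
        parts.append(bg_str[bg_pos : bg_pos + gap])
        bg_pos += gap
        strand = plan.strand or ("+" if rng.random() < 0.5 else "-")
        parts.append(nt if strand == "+" else _codec.revcomp(nt))
        final_cassettes.append(
            Cassette(plan.gene_kind, start, end, strand, query.query_id)
        )
        prev_end = end
    parts.append(bg_str[bg_pos:])
    sequence = "".join(parts)
    assert len(sequence) == length

    return Genome(
        pop_id=pop_id,
        sequence=sequence,
        realized_gc=_codec.gc_fraction(sequence),
        cassettes=final_cassettes,
        notes=notes,
    )


def couple_virus_gc(
    host_gc: float,
    offset_mean: float = -0.017,
    offset_sd: float = 0.01,
    seed: int = 0,
) -> float:
    """Virus GC drawn around its host's GC (virus and host GC correlate).

    The default offset of -1.7 GC percentage points maps 38 mol% hosts onto
    ~36.3 mol% viruses. The draw is clamped to the generable GC range.
    """
    rng = np.random.default_rng(seed)
    gc = host_gc + offset_mean + (offset_sd * rng.standard_normal() if offset_sd else 0.0)
    return float(min(max(gc, GC_RANGE[0]), GC_RANGE[1]))


# ---------------------------------------------------------------------------
# scenario preset


@dataclass
class ScenarioConfig:
    """Parameters of the default two-soil study design.

    Genome lengths are scaled-down (tens of kb) relative to real prokaryote
    chromosomes so a full study runs quickly; what matters downstream is GC,
    labelling and relative abundance, all of which are preserved.
    """

    soils: tuple[str, ...] = SOILS
    replicates: int = 3
    n_active_aoa: int = 4
    n_inactive_aoa: int = 1
    aoa_gc: tuple[float, ...] = (0.372, 0.378, 0.383, 0.388)
    inactive_aoa_gc: float = 0.380
    aoa_lengths: tuple[int, ...] = (80_000, 70_000, 90_000, 60_000)
    inactive_aoa_length: int = 75_000
    aoa_abundance: float = 0.03
    background_gc: tuple[float, ...] = (0.57, 0.62, 0.67)
    background_lengths: tuple[int, ...] = (100_000, 100_000, 100_000)
    background_abundance: tuple[float, ...] = (0.30, 0.27, 0.20)
    virus_lengths: tuple[int, ...] = (8_000, 18_000, 28_000, 38_000, 48_000)
    virus_temperate: tuple[bool, ...] = (False, True, True, False, True)
    #: index (into the soil's AOA hosts, actives first) of each virus's host;
    #: index n_active_aoa is the inactive host
    virus_host_index: tuple[int, ...] = (0, 1, 2, 4, 3)
    virus_abundance: float = 0.016
    virus_gc_offset_mean: float = -0.017
    virus_gc_offset_sd: float = 0.01
    atom13c_active: float = 1.0
    host_cassettes: tuple[str, ...] = ("integrase", "mco1")
    n_viruses: int | None = None  # None -> len(virus_lengths); 0 -> no viruses


def _soil_tag(soil: str) -> str:
    return soil.replace("pH", "s").replace(".", "")


def build_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Build the default two-soil scenario with known ground truth.

    Per soil: ``n_active_aoa`` autotrophic low-GC AOA hosts, ``n_inactive_aoa``
    dormant AOA, a high-GC unlabeled background block holding most abundance,
    and viruses whose GC is coupled to their host's. Populations — and hence
    activity — are disjoint between soils. Viruses inherit their host's
    labelling state (carbon flows from host to virus during infection).
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    n_vir = len(config.virus_lengths) if config.n_viruses is None else config.n_viruses

    populations: list[PopulationSpec] = []
    genomes: dict[str, Genome] = {}

    for soil in config.soils:
        tag = _soil_tag(soil)
        hosts: list[PopulationSpec] = []

        # active AOA hosts
        for i in range(config.n_active_aoa):
            pid = f"{tag}-aoa{i + 1}"
            gc = config.aoa_gc[i % len(config.aoa_gc)]
            length = config.aoa_lengths[i % len(config.aoa_lengths)]
            pop = PopulationSpec(
                pop_id=pid,
                guild="AOA_host",
                gc_target=gc,
                genome_length=length,
                abundance={soil: config.aoa_abundance},
                active={t: True for t in TREATMENTS},
                atom13c=config.atom13c_active,
            )
            populations.append(pop)
            hosts.append(pop)
        # inactive (dormant) AOA
        for i in range(config.n_inactive_aoa):
            pid = f"{tag}-aoaX{i + 1}"
            pop = PopulationSpec(
                pop_id=pid,
                guild="AOA_host",
                gc_target=config.inactive_aoa_gc,
                genome_length=config.inactive_aoa_length,
                abundance={soil: config.aoa_abundance},
                active={t: False for t in TREATMENTS},
                atom13c=config.atom13c_active,
            )
            populations.append(pop)
            hosts.append(pop)
        # high-GC unlabeled background block
        for i, (gc, length, ab) in enumerate(
            zip(config.background_gc, config.background_lengths, config.background_abundance)
        ):
            populations.append(
                PopulationSpec(
                    pop_id=f"{tag}-bg{i + 1}",
                    guild="background",
                    gc_target=gc,
                    genome_length=length,
                    abundance={soil: ab},
                    active={t: False for t in TREATMENTS},
                    atom13c=NATURAL_13C,
                )
            )
        # viruses, GC coupled to host GC
        viruses: list[PopulationSpec] = []
        for i in range(n_vir):
            host = hosts[config.virus_host_index[i % len(config.virus_host_index)] % len(hosts)]
            gc = couple_virus_gc(
                host.gc_target,
                config.virus_gc_offset_mean,
                config.virus_gc_offset_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            viruses.append(
                PopulationSpec(
                    pop_id=f"{tag}-vir{i + 1}",
                    guild="virus",
                    gc_target=gc,
                    genome_length=config.virus_lengths[i % len(config.virus_lengths)],
                    abundance={soil: config.virus_abundance},
                    active=dict(host.active),
                    atom13c=host.atom13c,
                    host_id=host.pop_id,
                    temperate=config.virus_temperate[i % len(config.virus_temperate)],
                )
            )
        populations.extend(viruses)

        # normalise this soil's abundances to the simplex
        soil_pops = hosts + [p for p in populations if p.abundance.get(soil) and p.guild == "background"] + viruses
        total = sum(p.abundance[soil] for p in soil_pops)
        if total <= 0:
            raise ValueError(f"soil {soil}: abundance vector not normalizable")
        for p in soil_pops:
            p.abundance[soil] = p.abundance[soil] / total

    # genomes; each cassette draws a distinct hallmark fixture (round-robin
    # per kind) so no two genomes carry identical back-coded cassette DNA,
    # which would cross-recruit reads between unrelated contigs
    alloc = _FixtureAllocator("AOA")
    mco1_done: set[str] = set()
    for pop in populations:
        plans: list[CassettePlan] = []
        if pop.guild == "AOA_host":
            plans = [
                CassettePlan(kind, query_id=alloc.take(kind))
                for kind in config.host_cassettes
            ]
        elif pop.is_virus():
            plans = [
                CassettePlan("capsid", query_id=alloc.take("capsid")),
                CassettePlan("terminase", query_id=alloc.take("terminase")),
            ]
            if pop.genome_length >= 20_000:
                plans.append(CassettePlan("portal", query_id=alloc.take("portal")))
            if pop.temperate:
                plans.append(CassettePlan("integrase", query_id=alloc.take("integrase")))
            soil = next(iter(pop.abundance))
            if pop.active.get("13C", False) and soil not in mco1_done:
                # one labelled virus per soil carries the MCO1 AMG
                plans.append(CassettePlan("mco1", query_id=alloc.take("mco1")))
                mco1_done.add(soil)
        genomes[pop.pop_id] = generate_genome(
            length=pop.genome_length,
            gc_target=pop.gc_target,
            cassettes=plans,
            seed=int(rng.integers(0, 2**31 - 1)),
            pop_id=pop.pop_id,
            notes=f"guild={pop.guild}",
        )

    scenario = Scenario(populations=populations, genomes=genomes, replicates=config.replicates)
    scenario.validate()
    return scenario


class _FixtureAllocator:
    """Deal out hallmark fixtures of one guild round-robin per gene kind.

    Population order is deterministic, so allocation is too. Wraps around
    if demand exceeds the fixture supply (only possible in custom presets
    far larger than the default design).
    """

    def __init__(self, guild: str) -> None:
        self.guild = guild
        self._next: dict[str, int] = {}

    def take(self, kind: str) -> str:
        options = hallmarks_by_kind(kind, self.guild)
        i = self._next.get(kind, 0)
        self._next[kind] = i + 1
        return options[i % len(options)].query_id


def hash_stable(text: str) -> int:
    """Process-stable string hash (unlike builtin hash, not salted)."""
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


# ---------------------------------------------------------------------------
# serialization


def write_genomes_fasta(scenario: Scenario, path) -> None:
    """Multi-FASTA, one record per population.

    Header: ``pop_id|guild|gc|active_<soil>`` — the ground-truth annotation
    downstream tests use; pipeline calls never parse it.
    """
    with open(path, "w") as fh:
        for pop in scenario.populations:
            genome = scenario.genomes[pop.pop_id]
            soils = ",".join(f"active_{s}={pop.active.get('13C', False)}" for s in pop.abundance)
            fh.write(f">{pop.pop_id}|{pop.guild}|{genome.realized_gc:.4f}|{soils}\n")
            seq = genome.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_cassettes_gff3(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pop in scenario.populations:
            genome = scenario.genomes[pop.pop_id]
            for c in genome.cassettes:
                # GFF3 is 1-based, closed intervals
                fh.write(
                    f"{pop.pop_id}\thybridsip\tgene\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t.\tID={pop.pop_id}:{c.gene_kind};kind={c.gene_kind};"
                    f"query={c.query_id}\n"
                )


def scenario_to_dict(scenario: Scenario) -> dict:
    pops = []
    for p in scenario.populations:
        d = dataclasses.asdict(p)
        pops.append(d)
    return {"replicates": scenario.replicates, "populations": pops}


def write_scenario_yaml(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)
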