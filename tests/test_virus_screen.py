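"""ORF detection, hallmark homology search, and vOTU calling rules."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from hybridsip import ContigSet, call_votus, find_orfs, hallmark_search
from hybridsip import _codec
from hybridsip.hallmarks import backtranslate, hallmarks_by_kind, load_hallmarks
from hybridsip.mapping import Contig, MappingResult
from hybridsip.virus_screen import (
    DEFAULT_SCORE_THRESHOLD,
    ORF,
    screen_contigs,
)

from conftest import make_library  # noqa: F401  (shared helpers live here)


def _random_seq(rng, n, p=None):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# independent six-frame ORF scanner: brute force over every start codon


def _oracle_orfs(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    starts = {"ATG", "GTG", "TTG"}
    stops = {"TAA", "TAG", "TGA"}
    found = {}
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else _codec.revcomp(seq)
        for i in range(L - 2):
            if s[i : i + 3] not in starts:
                continue
            j = i + 3
            while j + 3 <= L:
                if s[j : j + 3] in stops:
                    break
                j += 3
            else:
                continue
            if s[j : j + 3] not in stops:
                continue
            if (j - i) // 3 < min_aa:
                continue
            # keep only the leftmost start per (strand, stop)
            key = (strand, j)
            if key not in found or i < found[key]:
                found[key] = i
    out = set()
    for (strand, j), i in found.items():
        if strand == "+":
            out.add((i, j + 3, "+"))
        else:
            out.add((L - (j + 3), L - i, "-"))
    return out


class TestFindOrfs:
    def test_no_start_codons_no_orfs(self):
        assert find_orfs("CCC" * 200, min_aa=30) == []

    def test_constructed_reverse_strand_orf(self):
        rng = np.random.default_rng(1)
        protein = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSVWY"), size=99))
        nt = backtranslate(protein, 0.5)
        pad5, pad3 = "CCC" * 40, "CCC" * 30
        contig = pad5 + _codec.revcomp(nt) + pad3
        orfs = [o for o in find_orfs(contig, min_aa=90) if o.strand == "-"]
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.start == len(pad5)
        assert orf.end == len(pad5) + len(nt)
        assert orf.protein == protein

    @pytest.mark.parametrize("gc", [0.35, 0.5])
    def test_matches_bruteforce_scanner_on_random_sequence(self, gc):
        rng = np.random.default_rng(11)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = _random_seq(rng, 30_000, p=p)
        got = {(o.start, o.end, o.strand) for o in find_orfs(seq, min_aa=100)}
        assert got == _oracle_orfs(seq, 100)

    def test_min_aa_floor(self):
        with pytest.raises(ValueError):
            find_orfs("ATGAAATAA", min_aa=10)


# ---------------------------------------------------------------------------
# independent affine-gap Smith-Waterman (Gotoh), same gap convention as the
# implementation: a gap of length L scores open + (L-1)*extend


def _sw_score(a: str, b: str, open_=-11.0, extend=-1.0) -> float:
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + open_, E[i, j - 1] + extend)
            F[i, j] = max(H[i - 1, j] + open_, F[i - 1, j] + extend)
            sub = H[i - 1, j - 1] + blosum[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


class TestHallmarkSearch:
    def test_exact_copy_scores_the_self_alignment_score(self):
        query = min(hallmarks_by_kind("capsid"), key=lambda h: len(h.seq))
        orf = ORF(0, 3 * len(query.seq) + 3, "+", 0, query.seq)
        hits = hallmark_search([orf], score_threshold=50.0)
        capsid = [h for h in hits if h.gene_kind == "capsid"]
        assert len(capsid) == 1
        assert capsid[0].query_id == query.query_id
        assert capsid[0].score == pytest.approx(_sw_score(query.seq, query.seq))

    def test_partial_alignment_agrees_with_independent_gotoh(self):
        query = min(hallmarks_by_kind("portal"), key=lambda h: len(h.seq))
        rng = np.random.default_rng(2)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        # half the query embedded in random sequence
        fragment = query.seq[: len(query.seq) // 2]
        protein = "".join(rng.choice(aa, 30)) + fragment + "".join(rng.choice(aa, 30))
        orf = ORF(0, 3 * len(protein) + 3, "+", 0, protein)
        hits = [h for h in hallmark_search([orf], score_threshold=50.0) if h.query_id == query.query_id]
        assert hits
        assert hits[0].score == pytest.approx(_sw_score(protein, query.seq))

    def test_random_orfs_rarely_hit_at_default_threshold(self):
        rng = np.random.default_rng(3)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        n_hit = 0
        for _ in range(100):
            protein = "".join(rng.choice(aa, 200))
            orf = ORF(0, 603, "+", 0, protein)
            if hallmark_search([orf], score_threshold=DEFAULT_SCORE_THRESHOLD):
                n_hit += 1
        assert n_hit <= 1  # no hit in >= 99% of trials

    def test_empty_orf_list(self):
        assert hallmark_search([], score_threshold=50.0) == []

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            hallmark_search([], hallmark_db=(), score_threshold=50.0)


def _mock_mapping(contig_ids, lengths, depth, breadth, lib="pH4.5_13C_HBD_r1"):
    n = len(contig_ids)
    return {
        lib: MappingResult(
            library_id=lib,
            contig_ids=list(contig_ids),
            lengths=np.array(lengths),
            counts=np.full(n, 100),
            depth=np.full(n, float(depth)),
            breadth=np.full(n, float(breadth)),
            unmapped=0,
            total_reads=100 * n,
        )
    }


def _cassette_contig(length, gc, kinds, seed, cid="c1"):
    from hybridsip import CassettePlan, generate_genome

    g = generate_genome(length, gc, [CassettePlan(k) for k in kinds], seed=seed)
    return Contig(contig_id=cid, sequence=g.sequence, source_pop_id="v", start=0, end=length)


class TestCallVotus:
    def _call(self, contig, **kw):
        contigs = ContigSet([contig], min_contig_length=5_000)
        hits = screen_contigs(contigs)
        mappings = _mock_mapping([contig.contig_id], [len(contig)], kw.pop("depth", 3.0), kw.pop("breadth", 0.9))
        return call_votus(contigs, hits, mappings, **kw)

    def test_short_contig_with_capsid_not_a_votu(self):
        votus = self._call(_cassette_contig(8_000, 0.36, ["capsid"], seed=1))
        assert votus == []

    def test_terminase_plus_integrase_makes_temperate_votu(self):
        votus = self._call(_cassette_contig(20_000, 0.36, ["terminase", "integrase"], seed=2))
        assert len(votus) == 1
        v = votus[0]
        assert v.temperate_predicted
        assert v.host_guild_prediction == "AOA"
        assert all(v.passes_filters.values())

    def test_integrase_alone_never_triggers_a_call(self):
        votus = self._call(_cassette_contig(20_000, 0.36, ["integrase"], seed=3))
        assert votus == []

    def test_gc_mismatch_downgrades_guild_to_unknown(self):
        votus = self._call(
            _cassette_contig(20_000, 0.55, ["capsid"], seed=4), gc_tolerance=0.05
        )
        assert len(votus) == 1
        assert votus[0].host_guild_prediction == "unknown"

    def test_failing_breadth_filter_recorded_per_library(self):
        contig = _cassette_contig(20_000, 0.36, ["capsid"], seed=5)
        contigs = ContigSet([contig], min_contig_length=5_000)
        hits = screen_contigs(contigs)
        mappings = _mock_mapping(["c1"], [20_000], depth=3.0, breadth=0.5)
        votus = call_votus(contigs, hits, mappings)
        assert votus[0].passes_filters == {"pH4.5_13C_HBD_r1": False}


class TestScenarioLevelProperties:
    def test_all_calls_are_virus_derived_and_eligible_viruses_called(self, default_study):
        confusion = default_study.votu_confusion()
        assert confusion["fp"] == 0  # no host contig called
        assert confusion["fn"] == 0  # every eligible cassette-bearing contig called

    def test_temperate_prediction_matches_truth_when_integrase_on_contig(self, default_study):
        sc = default_study.scenario
        for v in default_study.votus:
            contig = default_study.contigs.get(v.contig_id)
            genome = sc.genomes[contig.source_pop_id]
            integrase_on_contig = any(
                c.gene_kind == "integrase" and contig.start <= c.start and c.end <= contig.end
                for c in genome.cassettes
            )
            if integrase_on_contig:
                assert v.temperate_predicted
                assert sc.population(contig.source_pop_id).temperate

    def test_votu_gc_reproduces_host_coupling_offset(self, default_study):
        sc = default_study.scenario
        votu_gc = [v.gc for v in default_study.votus if v.host_guild_prediction == "AOA"]
        aoa_gc = [
            sc.genomes[p.pop_id].realized_gc
            for p in sc.populations
            if p.guild == "AOA_host"
        ]
        offset = np.mean(votu_gc) - np.mean(aoa_gc)
        assert abs(offset - (-0.017)) <= 0.01

    def test_zero_virus_scenario_yields_no_calls(self):
        from hybridsip import ScenarioConfig, build_scenario

        sc = build_scenario(ScenarioConfig(n_viruses=0), seed=1)
        host = next(p for p in sc.populations if p.guild == "AOA_host")
        genome = sc.genomes[host.pop_id]
        contig = Contig("c1", genome.sequence[:20_000], host.pop_id, 0, 20_000)
        contigs = ContigSet([contig], min_contig_length=5_000)
        hits = screen_contigs(contigs)
        mappings = _mock_mapping(["c1"], [20_000], 3.0, 0.9)
        assert call_votus(contigs, hits, mappings) == []
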