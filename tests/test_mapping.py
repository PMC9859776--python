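"""Contig recovery surrogate and k-mer mapping vs a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from hybridsip import (
    ContigSet,
    DesignViolationError,
    feature_proportions,
    generate_genome,
    map_reads,
    recover_contigs,
    sample_reads,
)
from hybridsip import _codec
from hybridsip.mapping import Contig, mag_features

from conftest import make_library


def _contig(cid: str, seq: str, pop: str = "p", start: int = 0) -> Contig:
    return Contig(contig_id=cid, sequence=seq, source_pop_id=pop, start=start, end=start + len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# brute-force oracle: per read, count read k-mer positions whose canonical
# k-mer occurs anywhere in each contig; assign to the max (ties: smallest id)


def _oracle_assign(read: str, contigs: list[Contig], k: int) -> str | None:
    def canon(kmer: str) -> str:
        return min(kmer, _codec.revcomp(kmer))

    contig_sets = {
        c.contig_id: {
            canon(c.sequence[i : i + k]) for i in range(len(c.sequence) - k + 1)
        }
        for c in contigs
    }
    best_id, best_n = None, 0
    for cid in sorted(contig_sets):
        n = sum(
            1
            for i in range(len(read) - k + 1)
            if canon(read[i : i + k]) in contig_sets[cid]
        )
        if n > best_n:
            best_id, best_n = cid, n
    return best_id


class TestMapReadsOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_assignment_matches_bruteforce_on_toys(self, seed):
        rng = np.random.default_rng(seed)
        contigs = ContigSet(
            [_contig(f"c{i}", _random_seq(rng, 6_000), pop=f"p{i}") for i in range(5)],
            min_contig_length=5_000,
        )
        reads = []
        for _ in range(150):
            c = contigs.contigs[rng.integers(0, 5)]
            start = rng.integers(0, len(c.sequence) - 80)
            reads.append(c.sequence[start : start + 80])
        for _ in range(50):
            reads.append(_random_seq(rng, 80))  # junk: should be unmapped
        lib = make_library(reads)
        result = map_reads(lib, contigs, k=21)
        count_by_contig = dict(zip(result.contig_ids, result.counts))
        expected_counts = {cid: 0 for cid in result.contig_ids}
        n_unmapped = 0
        for read in reads:
            cid = _oracle_assign(read, contigs.contigs, 21)
            if cid is None:
                n_unmapped += 1
            else:
                expected_counts[cid] += 1
        assert count_by_contig == expected_counts
        assert result.unmapped == n_unmapped

    def test_exact_reads_map_back_to_their_source(self):
        rng = np.random.default_rng(3)
        contigs = ContigSet(
            [_contig(f"c{i}", _random_seq(rng, 5_000), pop=f"p{i}") for i in range(3)],
            min_contig_length=5_000,
        )
        reads, truth = [], []
        for _ in range(300):
            i = rng.integers(0, 3)
            c = contigs.contigs[i]
            start = rng.integers(0, len(c.sequence) - 100)
            reads.append(c.sequence[start : start + 100])
            truth.append(c.contig_id)
        lib = make_library(reads)
        result = map_reads(lib, contigs, k=21)
        # every error-free read shares all its k-mers with its source contig
        assert result.counts.sum() == 300
        assert result.unmapped == 0


class TestDepthBreadth:
    def test_end_to_end_tiling_breadth(self):
        rng = np.random.default_rng(4)
        seq = _random_seq(rng, 10_000)
        contigs = ContigSet([_contig("c1", seq)], min_contig_length=5_000)
        reads = [seq[i * 150 : (i + 1) * 150] for i in range(66)]  # covers 9,900 bp
        lib = make_library(reads)
        result = map_reads(lib, contigs, k=21)
        count, depth, breadth = result.per_contig("c1")
        assert count == 66
        assert breadth == pytest.approx(0.99)
        assert depth == pytest.approx(66 * 150 / 10_000)

    def test_zero_read_library(self):
        rng = np.random.default_rng(5)
        contigs = ContigSet([_contig("c1", _random_seq(rng, 5_000))], min_contig_length=5_000)
        lib = make_library([])
        lib.read_length = 150
        result = map_reads(lib, contigs, k=21)
        assert result.counts.sum() == 0
        assert (result.breadth == 0).all()

    def test_k_larger_than_read_rejected(self):
        rng = np.random.default_rng(6)
        contigs = ContigSet([_contig("c1", _random_seq(rng, 5_000))], min_contig_length=5_000)
        lib = make_library([_random_seq(rng, 20)])
        with pytest.raises(ValueError, match="exceeds read length"):
            map_reads(lib, contigs, k=21)

    def test_breadth_depth_consistency_everywhere(self, default_study):
        rl = default_study.config.sequencing.read_length
        for result in default_study.mappings.values():
            assert (result.breadth >= 0).all() and (result.breadth <= 1).all()
            cap = np.minimum(1.0, result.counts * rl / result.lengths)
            assert (result.breadth <= cap + 1e-12).all()
            assert (result.depth >= result.breadth - 1e-12).all()  # >=1x where covered


class TestRecoverContigs:
    @pytest.fixture()
    def genomes(self):
        return {
            "hi": generate_genome(30_000, 0.4, seed=1, pop_id="hi"),
            "lo": generate_genome(30_000, 0.4, seed=2, pop_id="lo"),
        }

    def _libs(self, genomes, n=3, depth=2_000):
        # 'hi' gets ~95% of mass -> high depth; 'lo' trace -> below threshold
        mass = pd.Series({"hi": 0.95, "lo": 0.05})
        return [
            sample_reads(
                mass,
                genomes,
                depth=depth,
                seed=s,
                library_id=f"pH4.5_12C_LBD_r{s + 1}",
                soil="pH4.5",
                treatment="12C",
                pool="LBD",
                replicate=s + 1,
            )
            for s in range(n)
        ]

    def test_depth_threshold_gates_recovery(self, genomes):
        libs = self._libs(genomes)
        contigs = recover_contigs(libs, genomes, min_depth=5.0, seed=0)
        sources = {c.source_pop_id for c in contigs}
        assert sources == {"hi"}  # 'lo' pooled depth ~1.5x < 5x

    def test_zero_depth_population_yields_nothing(self, genomes):
        libs = self._libs(genomes)
        extra = {"z": generate_genome(20_000, 0.5, seed=9, pop_id="z")}
        contigs = recover_contigs(libs, {**genomes, **extra}, min_depth=5.0, seed=0)
        assert all(c.source_pop_id != "z" for c in contigs)

    def test_fragments_partition_genome_and_respect_min_length(self, genomes):
        libs = self._libs(genomes)
        contigs = recover_contigs(libs, genomes, min_depth=5.0, seed=0)
        pieces = sorted((c.start, c.end) for c in contigs if c.source_pop_id == "hi")
        assert pieces[0][0] == 0 and pieces[-1][1] == 30_000
        for (s1, e1), (s2, _) in zip(pieces, pieces[1:]):
            assert e1 == s2
        assert all(e - s >= 5_000 for s, e in pieces)

    def test_invariant_to_library_order(self, genomes):
        libs = self._libs(genomes)
        a = recover_contigs(libs, genomes, min_depth=5.0, seed=0)
        b = recover_contigs(libs[::-1], genomes, min_depth=5.0, seed=0)
        assert [(c.contig_id, c.sequence) for c in a] == [
            (c.contig_id, c.sequence) for c in b
        ]

    def test_non_lbd_library_rejected(self, genomes):
        libs = self._libs(genomes)
        libs[0].pool = "HBD"
        with pytest.raises(DesignViolationError):
            recover_contigs(libs, genomes, min_depth=5.0, seed=0)
        libs[0].pool = "LBD"
        libs[0].treatment = "13C"
        with pytest.raises(DesignViolationError):
            recover_contigs(libs, genomes, min_depth=5.0, seed=0)


class TestFeatureProportions:
    def _setup(self):
        rng = np.random.default_rng(8)
        seqs = {f"c{i}": _random_seq(rng, 5_000) for i in range(2)}
        contigs = ContigSet(
            [
                _contig("c0", seqs["c0"], pop="A"),
                _contig("c1", seqs["c1"], pop="B"),
            ],
            min_contig_length=5_000,
        )
        return rng, seqs, contigs

    def test_quarter_of_reads_from_one_feature(self):
        rng, seqs, contigs = self._setup()
        reads = [seqs["c0"][i : i + 100] for i in range(250)]
        reads += [_random_seq(rng, 100) for _ in range(750)]
        lib = make_library(reads)
        mapping = map_reads(lib, contigs, k=21)
        props = feature_proportions(mapping, lib, {"A": ["c0"], "B": ["c1"]})
        assert props["A"] == pytest.approx(0.25)
        assert props["B"] == 0.0

    def test_partition_plus_unmapped_sums_to_one(self):
        rng, seqs, contigs = self._setup()
        reads = [seqs["c0"][i : i + 100] for i in range(100)]
        reads += [seqs["c1"][i : i + 100] for i in range(50)]
        reads += [_random_seq(rng, 100) for _ in range(50)]
        lib = make_library(reads)
        mapping = map_reads(lib, contigs, k=21)
        props = feature_proportions(mapping, lib, {"A": ["c0"], "B": ["c1"]})
        total = props.sum() + mapping.unmapped / lib.depth
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_depth_library_rejected(self):
        _, _, contigs = self._setup()
        lib = make_library([])
        lib.read_length = 100
        mapping = map_reads(lib, contigs, k=21)
        with pytest.raises(ValueError, match="zero-depth"):
            feature_proportions(mapping, lib, {"A": ["c0"]})

    def test_mag_features_group_by_provenance(self, default_study):
        feats = mag_features(
            default_study.contigs,
            [p.pop_id for p in default_study.scenario.populations if p.guild.endswith("_host")],
        )
        for fid, cids in feats.items():
            pop = fid.removeprefix("MAG:")
            assert all(default_study.contigs.get(c).source_pop_id == pop for c in cids)
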