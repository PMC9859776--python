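# Methods

## The problem this package models

In soil, autotrophic ammonia-oxidising archaea (AOA) and the viruses that
infect them have low-GC genomes (~38 and ~36 mol% GC respectively), while the
bulk of the community has much higher GC (>57 mol%). In a DNA stable-isotope
probing (SIP) experiment, organisms that assimilate ¹³CO₂-derived carbon build
¹³C into their DNA, raising its buoyant density (BD) in an isopycnic CsCl
gradient. The catch: the density gain from full ¹³C labelling (~0.036 g/ml)
is about the same as the gain from ~37 extra GC percentage points, so fully
labelled low-GC AOA DNA *co-migrates* with unlabelled high-GC background DNA
in the heavy fractions. Sequencing the heavy pool alone therefore yields
poor AOA assemblies drowned in background.

The hybrid design this package implements splits the roles of the two pools:

1. **Assemble from the light pool.** In the ¹²C control, *all* low-GC DNA —
   active or dormant AOA and their viruses — bands below 1.699 g/ml (LBD),
   cleanly separated from the high-GC background. Contigs are recovered from
   ¹²C LBD libraries only.
2. **Infer activity from the heavy pool.** Reads from the >1.719 g/ml (HBD)
   pools of both ¹²C and ¹³C incubations are mapped onto the LBD contigs.
   A feature recruiting a significantly greater proportion of reads in the
   ¹³C HBD libraries than in the ¹²C HBD libraries must carry ¹³C — it was
   active, or (for a virus) infected an active host that passed carbon on.

Everything runs against a synthetic community with known ground truth, so
sensitivity and specificity of the whole chain are measurable.

## Gradient model

BD is modelled with a Schildkraut-type linear relation plus a labelling term:

    BD = 1.660 + 0.098·GC + 0.036·(a − a₀)/(1 − a₀)   [g/ml]

with `a` the atom fraction ¹³C and `a₀ = 0.011` natural abundance. The
intercept (1.660), GC slope (0.098) and full-labelling shift (0.036) are
standard literature constants and are config-overridable; the source study
states the dependence only qualitatively. Key consequences under defaults:
unlabelled 38 mol% DNA bands at 1.6972, labelled at 1.7332; unlabelled
67 mol% DNA at 1.7257 — hence co-migration above the HBD cut and clean
separation below the LBD cut.

Each population's band is a Gaussian in density (σ = 0.003 g/ml, a diffusion-
broadening stand-in; fragment-length dependence is out of scope), integrated
over a discrete fraction scheme and renormalized over the scheme's span so
mass is conserved to machine precision. Inter-gradient variation is modelled
as Normal(0, 0.0005 g/ml) jitter on each band centre per replicate.

**Fraction scheme.** 24 equal fractions of 0.005 g/ml over [1.66, 1.78].
Pools select whole fractions by midpoint (LBD: midpoint < 1.699; HBD:
midpoint > 1.719), mirroring how discrete gradient fractions are pooled at
the bench. The 0.005 width is chosen so neither pooling cut coincides with a
fraction midpoint; with 0.006-wide fractions the 1.699 cut lands exactly on
a midpoint and the boundary fraction's membership becomes an artefact of
tie-breaking.

## Synthetic community

Defaults per soil (pH 4.5 and pH 7.5, fully disjoint populations):

| block | n | GC | length | abundance | labelled |
|---|---|---|---|---|---|
| active AOA hosts | 4 | 0.372–0.388 | 60–90 kb | 3% each | yes (a = 1.0) |
| dormant AOA host | 1 | 0.380 | 75 kb | 3% | no |
| background | 3 | 0.57 / 0.62 / 0.67 | 100 kb | 77% total | no |
| viruses | 5 | host GC − 0.017 ± 0.01 | 8–48 kb | 1.6% each | follows host |

Genome lengths are deliberately scaled down from real chromosomes (what
matters downstream is GC, labelling state and relative abundance, and a full
24-library study must run in seconds, a problem-size choice stated here as
the package's own). The labelling efficiency of active populations defaults
to full (atom fraction 1.0) and is a free parameter, as are abundances — the
source data report neither. Virus GC is drawn as host GC + Normal(−0.017,
0.01), reproducing the observed ~36.3 vs ~38 mol% host/virus pairing; one
virus per soil infects the dormant host (an unlabelled virus, exercising the
false-positive side) and one 8 kb virus exercises the ≥10 kb vOTU filter
from below.

Genome sequences have an exact base composition outside cassettes: the G+C
count is set to hit the target GC after compensating for cassette GC, then
randomly permuted under the seed. Positions are exchangeable with no codon
or k-mer structure — the same property an i.i.d. draw would give — but the
±0.01 realized-GC tolerance holds at every genome length, which i.i.d.
sampling cannot guarantee below ~20 kb.

**Hallmark cassettes.** The package ships a fixed FASTA of synthetic protein
sequences (random draws from background amino-acid frequencies, fixed seed;
see `scripts/make_hallmark_fixtures.py`) standing in for a provirus-derived
hallmark database: capsid, large terminase, portal, integrase, and the
AOA-specific multicopper oxidase MCO1, annotated with a host guild (AOA/AOB/
NOB). They are surrogates: they carry no real homology signal, only a fixed,
reproducible target set for insertion and search. Every AOA host genome
carries an integrase and an MCO1 cassette (so integrase hits on host contigs
genuinely test the "integrase alone is not a virus" rule); viruses carry
capsid + terminase (+ portal if ≥20 kb, + integrase if temperate), and one
labelled virus per soil carries MCO1 as an auxiliary metabolic gene.
Cassettes are back-coded with, per residue, the sense codon closest in GC to
the genome target. Back-translation is deterministic, so each cassette-
bearing genome receives a *distinct* fixture (round-robin allocation) —
otherwise two genomes would share byte-identical cassette DNA and
cross-recruit reads.

## Sequencing and its simplifications

Libraries are multinomial draws over populations proportional to pooled DNA
mass (note: mass, not genome copy number — the two are conflated, which is
harmless here because no downstream quantity needs copy number), uniform
start positions on the linear genome, i.i.d. substitution errors at 0.001/bp,
single-end 150 bp reads, 50,000 reads per library, 24 libraries
(2 soils × 2 treatments × 2 pools × 3 replicates). No paired ends, indels,
GC bias, or duplicates — none of the downstream logic consumes them, so
passing tests say nothing about robustness to those artefacts.

## Contig recovery (assembly surrogate)

Real assembly is out of scope. The surrogate preserves the property the
design depends on — only populations whose DNA actually banded in the ¹²C
LBD pool at depth yield reference sequences: a population is recoverable iff
its pooled mean depth across the six ¹²C LBD libraries reaches 5×, and
recoverable genomes are emitted as 2–8 random contiguous fragments of
≥5 kb (seeded per population, so output is invariant to library order).
This is the one stage that reads ground-truth tags (it stands in for an
assembler that would see the reads); all downstream calls are truth-blind.
Consequence, faithfully reproduced: a fully labelled population with
negligible LBD mass in the ¹²C control would *not* be recovered — the
design's known blind spot. Fragmentation can also strand a virus's cassette
on one fragment, leaving its other fragments uncallable; only
cassette-bearing fragments are callable, mirroring partial-genome recovery.

## Read mapping

Alignment-free: a read is assigned to the contig sharing the most canonical
21-mers (exact matching; ties to the lexicographically smallest contig id;
no shared k-mer = unmapped). With 0.1% substitution errors a 150 bp read
retains long exact k-mer runs, so alignment adds nothing here. The
implementation is an open-addressing hash table walked by a numba kernel
(pure-numpy fallback with identical semantics, cross-checked in tests);
assignment is verified against a brute-force all-vs-all oracle on toy
instances. An assigned read is placed at the diagonal of its first matching
k-mer — all matching k-mers of a contig lie on one diagonal for
substitution-only reads — and contributes read-length bases (clipped at
contig ends) to mean depth (aligned bases / contig length) and breadth
(fraction of positions covered ≥1×). A k-mer shared by two contigs (random
collision, ~10⁻⁷ per pair of 1 M-k-mer contigs) is credited to its first
occurrence.

## Virus screen

Maximal ORFs (leftmost start ATG/GTG/TTG per in-frame stop, ≥100 aa, six
frames) are translated and locally aligned (BLOSUM62, gap open −11 /
extend −1, so a length-L gap costs 11 + (L−1)) against the hallmark set. The
score threshold of 80 was fixed once by empirical null calibration
(`calibrate_score_threshold`): random 200-aa ORFs score ≤ ~60 against the
fixture set while true cassette ORFs self-score in the hundreds. A cheap
shared-4-mer seed filter skips alignments that cannot reach the threshold.

vOTU rules: contig ≥10 kb AND ≥1 virion-module hit (capsid/terminase/
portal). Integrase alone never triggers a call — hosts encode integrases —
but marks a called vOTU as predicted temperate. Each called contig is its
own vOTU (no ANI clustering). Host-guild prediction takes the guild
annotation of the best-scoring hit, corroborated by |contig GC − guild mean
GC| ≤ 0.05 (guild means 0.38/0.53/0.60 for AOA/AOB/NOB), else `unknown`.
Per-library detection filters (mean depth ≥1×, breadth ≥75%) are recorded
per vOTU and gate the heatmap.

## Inference

Per feature (MAG-analog = a recovered population's contigs grouped by
provenance, binning being out of scope; or a single vOTU contig), the
¹³C-enrichment test compares HBD read proportions (counts / total library
reads) across n = 3 replicates per treatment: a two-sided F-test at α = 0.05
decides variance homogeneity (identical samples: homogeneous; one zero
variance: not); then pooled-variance Student's t or Welch's t with
Welch–Satterthwaite degrees of freedom, two-sided, plus the direction
requirement mean(¹³C) > mean(¹²C). Degenerate cases: both groups constant
and equal → p = 1; both constant, different → p = 0. No multiple-testing
correction by default (Benjamini–Hochberg by flag); proportions are tested
untransformed. The same machinery drives the between-soil contrast on ¹²C
LBD proportions of vOTUs. The heatmap reports ln(reads per kb) per vOTU ×
library, masking (never imputing) zero-count or filter-failing entries, so
ln(0) cannot occur.

Under the no-labelling null the observed enriched-call rate is ~0.02 — below
the nominal α = 0.05 because the call requires both p < α (two-sided) and
the right direction, which halves the null rate by symmetry.

## Determinism

Every stage's randomness flows from one master seed via stable SHA-256
hashing of (seed, stage label); identically-seeded runs write byte-identical
artefacts (asserted in tests). Floats in TSVs are formatted with `%.10g`.

## Known limitations

- The assembly and binning surrogates use ground-truth provenance; nothing
  is learned here about assembler behaviour on co-migrating DNA.
- Hallmark fixtures are random proteins: detection power against *diverged*
  real homologues is not modelled — search sensitivity in this artifact is
  effectively exact-match.
- The gradient model has no fragment-length or rotor physics; band width is
  a single σ.
- Host guild corroborations by GC use fixed guild means; real guild GC
  distributions overlap more.
- Paper-scale headline counts (dozens of vOTUs, >100 MAGs) require field
  metagenomes and are not reproduced; all guarantees are properties of the
  synthetic study design at the problem sizes above.
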