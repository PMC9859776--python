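"""End-to-end orchestration: simulate -> fractionate -> sequence -> recover
-> map -> screen -> test -> report.

``run_study`` executes the whole chain in memory and returns a StudyResult;
``run_pipeline`` additionally persists every stage's outputs into a run
directory (TSV/FASTA/GFF3/YAML/JSON) together with a manifest recording the
package version, the config hash and every derived stage seed, so a run is
reproducible and any single stage can be re-run from its persisted inputs.

Stage seeds are derived by stable hashing of (master seed, stage label), so
the full artefact tree is a pure function of the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_stats import (
    HeatmapMatrix,
    enrichment_table,
    heatmap_matrix,
    soil_differential,
)
from .community import (
    NATURAL_13C,
    Scenario,
    build_scenario,
    write_cassettes_gff3,
    write_genomes_fasta,
    write_scenario_yaml,
)
from .config import RunConfig, config_hash, derive_seed, save_config
from .gradient import (
    FractionScheme,
    GradientProfile,
    PoolSpec,
    pool_fractions,
    simulate_gradient,
)
from .mapping import (
    ContigSet,
    MappingResult,
    mag_features,
    map_reads,
    recover_contigs,
    write_contigs_fasta,
)
from .sequencing import ReadLibrary, sample_reads, write_reads_fasta
from .virus_screen import VOTUCall, call_votus, hits_to_frame, screen_contigs, votus_to_frame

logger = logging.getLogger(__name__)

HOST_GUILDS = ("AOA_host", "AOB_host", "NOB_host")
POOLS = ("LBD", "HBD")
TREATMENTS = ("12C", "13C")


def library_id(soil: str, treatment: str, pool: str, replicate: int) -> str:
    return f"{soil}_{treatment}_{pool}_r{replicate}"


@dataclass
class StudyResult:
    config: RunConfig
    scenario: Scenario
    scheme: FractionScheme
    profiles: dict[tuple[str, str, int], GradientProfile]
    pooled: dict[str, pd.Series]  # library_id -> per-population pooled mass
    libraries: dict[str, ReadLibrary]
    contigs: ContigSet
    mappings: dict[str, MappingResult]
    hits: list
    votus: list[VOTUCall]
    features: dict[str, list[str]]
    proportions: pd.DataFrame  # features x libraries
    activity: dict[str, pd.DataFrame]  # soil -> enrichment table
    soil_diff: pd.DataFrame
    heatmap: HeatmapMatrix
    seeds: dict[str, int] = field(default_factory=dict)

    # ---- ground-truth helpers (simulation mode only; used by reports/tests)

    def feature_truth(self) -> pd.DataFrame:
        return feature_truth_frame(self.scenario, self.contigs, self.features)

    def votu_confusion(self) -> dict[str, int]:
        return votu_confusion_counts(
            self.scenario,
            self.contigs,
            [v.contig_id for v in self.votus],
            self.config.virus.min_votu_length,
        )

    def soil_diff_accuracy(self) -> tuple[int, int]:
        """(correctly labelled, total) vOTUs in the between-soil contrast.

        Ground truth: every default-scenario virus is soil-specific, so a
        called vOTU's label should be its source population's home soil.
        """
        if not len(self.soil_diff):
            return 0, 0
        truth = self.feature_truth()
        correct = sum(
            int(truth.loc[row.feature_id, "soil"] == row.label)
            for row in self.soil_diff.itertuples()
        )
        return correct, len(self.soil_diff)

    def summary(self) -> dict:
        truth = self.feature_truth()
        enr = {
            soil: enrichment_confusion(table, truth, soil)
            for soil, table in self.activity.items()
        }
        return {
            "version": __version__,
            "n_populations": len(self.scenario.populations),
            "n_libraries": len(self.libraries),
            "n_contigs": len(self.contigs),
            "n_votus": len(self.votus),
            "n_temperate_votus": int(sum(v.temperate_predicted for v in self.votus)),
            "enrichment_confusion": enr,
            "votu_confusion": self.votu_confusion(),
            "soil_differential_counts": self.soil_diff["label"].value_counts().to_dict()
            if len(self.soil_diff)
            else {},
        }


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full hybrid-SIP chain in memory."""
    config.validate()
    seeds: dict[str, int] = {}

    def seed_for(label: str) -> int:
        s = derive_seed(config.master_seed, label)
        seeds[label] = s
        return s

    scenario = build_scenario(config.scenario, seed=seed_for("scenario"))
    g = config.gradient
    scheme = FractionScheme.default(g.n_fractions, g.span_low, g.span_high)
    bd_params = {
        "intercept": g.intercept,
        "gc_slope": g.gc_slope,
        "label_shift": g.label_shift,
        "natural": g.natural_13c,
    }
    soils = list(config.scenario.soils)
    reps = range(1, config.scenario.replicates + 1)

    profiles: dict[tuple[str, str, int], GradientProfile] = {}
    pooled: dict[str, pd.Series] = {}
    libraries: dict[str, ReadLibrary] = {}
    for soil in soils:
        for treatment in TREATMENTS:
            for rep in reps:
                prof = simulate_gradient(
                    scenario,
                    soil,
                    treatment,
                    rep,
                    scheme=scheme,
                    sigma=g.band_sigma,
                    jitter_sd=g.replicate_jitter_sd,
                    seed=seed_for(f"gradient:{soil}:{treatment}:{rep}"),
                    bd_params=bd_params,
                )
                profiles[(soil, treatment, rep)] = prof
                for pool in POOLS:
                    spec = PoolSpec(pool, lbd_max=g.lbd_max, hbd_min=g.hbd_min)
                    mass = pool_fractions(prof, spec)
                    lid = library_id(soil, treatment, pool, rep)
                    pooled[lid] = mass
                    libraries[lid] = sample_reads(
                        mass,
                        scenario.genomes,
                        depth=config.sequencing.depth,
                        read_length=config.sequencing.read_length,
                        error_rate=config.sequencing.error_rate,
                        seed=seed_for(f"reads:{lid}"),
                        library_id=lid,
                        soil=soil,
                        treatment=treatment,
                        pool=pool,
                        replicate=rep,
                    )

    # recover contigs from 12C LBD libraries only (the design's premise)
    lbd12 = [
        lib
        for lib in libraries.values()
        if lib.pool == "LBD" and lib.treatment == "12C"
    ]
    contigs = recover_contigs(
        sorted(lbd12, key=lambda l: l.library_id),
        scenario.genomes,
        min_depth=config.recovery.min_depth,
        min_contig_length=config.recovery.min_contig_length,
        max_fragments=config.recovery.max_fragments,
        min_fragments=config.recovery.min_fragments,
        seed=seed_for("recover"),
    )

    mappings = {
        lid: map_reads(libraries[lid], contigs, k=config.mapping.k)
        for lid in sorted(libraries)
    }

    hits = screen_contigs(
        contigs,
        min_aa=config.virus.min_orf_aa,
        score_threshold=config.virus.score_threshold,
    )
    votus = call_votus(
        contigs,
        hits,
        mappings,
        min_length=config.virus.min_votu_length,
        min_coverage=config.virus.min_coverage,
        min_breadth=config.virus.min_breadth,
        guild_gc=config.virus.guild_gc,
        gc_tolerance=config.virus.gc_tolerance,
    )

    # features: MAG-analog host groups plus one feature per vOTU contig
    host_ids = [p.pop_id for p in scenario.populations if p.guild in HOST_GUILDS]
    features = mag_features(contigs, host_ids)
    for v in votus:
        features[v.contig_id] = [v.contig_id]

    total_reads = {lid: libraries[lid].depth for lid in libraries}
    proportions, activity, soil_diff, heatmap = analysis_tables(
        mappings, total_reads, features, votus, config, soils, list(reps)
    )

    return StudyResult(
        config=config,
        scenario=scenario,
        scheme=scheme,
        profiles=profiles,
        pooled=pooled,
        libraries=libraries,
        contigs=contigs,
        mappings=mappings,
        hits=hits,
        votus=votus,
        features=features,
        proportions=proportions,
        activity=activity,
        soil_diff=soil_diff,
        heatmap=heatmap,
        seeds=seeds,
    )


def feature_truth_frame(
    scenario: Scenario, contigs: ContigSet, features: dict[str, list[str]]
) -> pd.DataFrame:
    """Ground truth per analysis feature: home soil, guild, labelled or not."""
    rows = []
    if not features:
        return pd.DataFrame(columns=["feature_id", "soil", "guild", "labeled"]).set_index(
            "feature_id"
        )
    contig_by_id = {c.contig_id: c for c in contigs}
    for fid in features:
        if fid.startswith("MAG:"):
            pop = scenario.population(fid[4:])
        else:
            pop = scenario.population(contig_by_id[fid].source_pop_id)
        rows.append(
            {
                "feature_id": fid,
                "soil": next(iter(pop.abundance)),
                "guild": pop.guild,
                "labeled": pop.atom_fraction("13C") > NATURAL_13C,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def enrichment_confusion(activity: pd.DataFrame, truth: pd.DataFrame, soil: str) -> dict[str, int]:
    """Confusion counts for enrichment calls vs ground-truth labelling.

    Restricted to features native to the given soil (a feature tested
    against the other soil's libraries is trivially absent there).
    """
    t = activity.set_index("feature_id").join(truth, how="inner")
    t = t[t["soil"] == soil]
    return {
        "tp": int(((t["enriched"]) & (t["labeled"])).sum()),
        "fp": int(((t["enriched"]) & (~t["labeled"])).sum()),
        "fn": int(((~t["enriched"]) & (t["labeled"])).sum()),
        "tn": int(((~t["enriched"]) & (~t["labeled"])).sum()),
    }


def votu_confusion_counts(
    scenario: Scenario,
    contigs: ContigSet,
    called_ids: list[str],
    min_votu_length: int,
) -> dict[str, int]:
    """vOTU-call confusion vs ground truth.

    A contig counts as a true positive if called and virus-derived, a false
    positive if called but host/background-derived; an uncalled contig is a
    false negative only when it was eligible (long enough AND retaining a
    complete virion-module cassette after fragmentation).
    """
    from .hallmarks import VIRION_KINDS

    called = set(called_ids)
    tp = fp = fn = tn = 0
    for c in contigs:
        pop = scenario.population(c.source_pop_id)
        genome = scenario.genomes[c.source_pop_id]
        has_virion_cassette = pop.is_virus() and any(
            cas.gene_kind in VIRION_KINDS and c.start <= cas.start and cas.end <= c.end
            for cas in genome.cassettes
        )
        eligible = len(c) >= min_votu_length and has_virion_cassette
        if c.contig_id in called:
            if pop.is_virus():
                tp += 1
            else:
                fp += 1
        elif eligible:
            fn += 1
        else:
            tn += 1
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def proportions_from_mappings(
    mappings: dict[str, MappingResult],
    total_reads: dict[str, int],
    features: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-feature read proportions (features x libraries) from mapping counts."""
    cols = {}
    for lid in sorted(mappings):
        m = mappings[lid]
        depth = total_reads[lid]
        if depth == 0:
            raise ValueError(f"library {lid} has zero reads")
        count_by_contig = dict(zip(m.contig_ids, m.counts))
        cols[lid] = {
            fid: sum(count_by_contig.get(cid, 0) for cid in cids) / depth
            for fid, cids in features.items()
        }
    return pd.DataFrame(cols)


def analysis_tables(
    mappings: dict[str, MappingResult],
    total_reads: dict[str, int],
    features: dict[str, list[str]],
    votus: list[VOTUCall],
    config: RunConfig,
    soils: list[str],
    reps: list[int],
):
    """The inference layer: proportions, enrichment, soil contrast, heatmap."""
    proportions = proportions_from_mappings(mappings, total_reads, features)

    # per-soil 13C-enrichment tests on HBD proportions
    activity: dict[str, pd.DataFrame] = {}
    for soil in soils:
        cols_12 = [library_id(soil, "12C", "HBD", r) for r in reps]
        cols_13 = [library_id(soil, "13C", "HBD", r) for r in reps]
        activity[soil] = enrichment_table(
            proportions[cols_12],
            proportions[cols_13],
            alpha=config.stats.alpha,
            variance_alpha=config.stats.variance_alpha,
            bh_correct=config.stats.bh_correct,
        )

    # between-soil contrast on (by default) 12C LBD proportions, vOTUs only
    votu_ids = [v.contig_id for v in votus]
    by_soil = {
        soil: proportions.loc[
            votu_ids,
            [
                library_id(soil, config.stats.soil_diff_treatment, config.stats.soil_diff_pool, r)
                for r in reps
            ],
        ]
        for soil in soils
    }
    soil_diff = (
        soil_differential(by_soil, alpha=config.stats.alpha, variance_alpha=config.stats.variance_alpha)
        if votu_ids
        else pd.DataFrame(columns=["feature_id", "label"])
    )

    heatmap = heatmap_matrix(
        mappings,
        votus,
        libraries=sorted(mappings),
        min_coverage=config.virus.min_coverage,
        min_breadth=config.virus.min_breadth,
    )
    return proportions, activity, soil_diff, heatmap


# ---------------------------------------------------------------------------
# persistence


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> StudyResult:
    """Run the full chain and persist every stage into a run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "config"
    try:
        save_config(config, out / "config.yaml")
        stage = "simulate"
        result = _run_and_persist(config, out)
    except Exception:
        logger.exception("pipeline aborted at stage %s (partial outputs in %s)", stage, out)
        raise
    return result


def _run_and_persist(config: RunConfig, out: Path) -> StudyResult:
    result = run_study(config)

    write_genomes_fasta(result.scenario, out / "genomes.fasta")
    write_cassettes_gff3(result.scenario, out / "cassettes.gff3")
    write_scenario_yaml(result.scenario, out / "scenario.yaml")

    gdir = out / "gradients"
    gdir.mkdir(exist_ok=True)
    for (soil, treatment, rep), prof in sorted(result.profiles.items()):
        _write_tsv(
            prof.to_frame(),
            gdir / f"{soil}_{treatment}_r{rep}.tsv",
            index=True,
        )
    pooled_df = pd.DataFrame(result.pooled).fillna(0.0)
    pooled_df.index.name = "pop_id"
    _write_tsv(pooled_df[sorted(pooled_df.columns)], out / "pooled_mass.tsv", index=True)

    if config.persist_reads:
        rdir = out / "reads"
        rdir.mkdir(exist_ok=True)
        for lid in sorted(result.libraries):
            write_reads_fasta(result.libraries[lid], rdir / f"{lid}.fasta")

    write_contigs_fasta(result.contigs, out / "contigs.fasta")
    _write_tsv(result.contigs.to_frame(), out / "contigs.tsv")

    mapping_df = pd.concat([m.to_frame() for _, m in sorted(result.mappings.items())])
    _write_tsv(mapping_df, out / "mapping.tsv")
    _write_tsv(library_stats(result.mappings), out / "library_stats.tsv")

    _write_tsv(hits_to_frame(result.hits), out / "hallmark_hits.tsv")
    _write_tsv(votus_to_frame(result.votus), out / "votus.tsv")

    prop = result.proportions.copy()
    prop.index.name = "feature_id"
    _write_tsv(prop, out / "feature_proportions.tsv", index=True)

    for soil, table in sorted(result.activity.items()):
        _write_tsv(table, out / f"activity_{soil.replace('.', '')}.tsv")
    _write_tsv(result.soil_diff, out / "soil_differential.tsv")
    _write_tsv(result.heatmap.values, out / "heatmap_values.tsv", index=True)
    _write_tsv(result.heatmap.mask, out / "heatmap_mask.tsv", index=True)

    manifest = {
        "version": __version__,
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
        "stage_seeds": dict(sorted(result.seeds.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "summary.json").write_text(
        json.dumps(result.summary(), indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return result


# ---------------------------------------------------------------------------
# study-level evaluations


def null_enrichment_rate(
    config: RunConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> tuple[float, int]:
    """Type-I error of the enrichment test under a no-labelling null.

    Rebuilds the default scenario with every population at natural 13C
    abundance, then repeatedly draws the replicate HBD library counts
    (multinomial over populations at the configured depth, with fresh
    inter-gradient jitter) and runs the enrichment test per population.
    Read sequences and mapping are bypassed — under this null they would
    reproduce the multinomial counts up to the (population-exclusive)
    k-mer assignment — so the rate isolates the inference layer.

    Returns (fraction of tests called enriched, number of tests).
    """
    from dataclasses import replace

    from .community import NATURAL_13C as NAT

    cfg = config or RunConfig()
    scen_cfg = replace(cfg.scenario, atom13c_active=NAT)
    scenario = build_scenario(scen_cfg, seed=derive_seed(seed, "null-scenario"))
    g = cfg.gradient
    scheme = FractionScheme.default(g.n_fractions, g.span_low, g.span_high)
    bd_params = {
        "intercept": g.intercept,
        "gc_slope": g.gc_slope,
        "label_shift": g.label_shift,
        "natural": g.natural_13c,
    }
    hbd = PoolSpec("HBD", lbd_max=g.lbd_max, hbd_min=g.hbd_min)
    depth = cfg.sequencing.depth
    reps = range(1, scen_cfg.replicates + 1)

    from .activity_stats import enrichment_test

    n_enriched = 0
    n_tests = 0
    for i in range(n_replicates):
        for soil in scen_cfg.soils:
            counts: dict[str, dict[str, np.ndarray]] = {}
            for treatment in TREATMENTS:
                for rep in reps:
                    lab = f"null:{i}:{soil}:{treatment}:{rep}"
                    prof = simulate_gradient(
                        scenario,
                        soil,
                        treatment,
                        rep,
                        scheme=scheme,
                        sigma=g.band_sigma,
                        jitter_sd=g.replicate_jitter_sd,
                        seed=derive_seed(seed, lab),
                        bd_params=bd_params,
                    )
                    mass = pool_fractions(prof, hbd)
                    p = mass.to_numpy()
                    p = p / p.sum()
                    rng = np.random.default_rng(derive_seed(seed, lab + ":counts"))
                    counts.setdefault(treatment, {})[rep] = rng.multinomial(depth, p)
                    pop_ids = list(mass.index)
            for j, pid in enumerate(pop_ids):
                x12 = np.array([counts["12C"][r][j] for r in reps]) / depth
                x13 = np.array([counts["13C"][r][j] for r in reps]) / depth
                if x12.sum() == 0 and x13.sum() == 0:
                    continue  # degenerate all-zero feature: p = 1 by definition
                call = enrichment_test(
                    x12, x13, alpha=cfg.stats.alpha, variance_alpha=cfg.stats.variance_alpha
                )
                n_tests += 1
                n_enriched += int(call.enriched)
    return n_enriched / max(n_tests, 1), n_tests


def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: RunConfig | None = None,
) -> dict:
    """Parameter recovery of the full chain over independent seeds.

    Runs the default two-soil study once per seed and aggregates:
    enrichment-call sensitivity / false-positive rate against ground-truth
    labelling, vOTU-call sensitivity (eligible contigs) and false calls,
    and between-soil label accuracy for called vOTUs.
    """
    cfg = config or RunConfig()
    enr = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    votu = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    sd_correct = sd_total = 0
    for i in range(n_seeds):
        from dataclasses import replace as _replace

        run_cfg = _replace(cfg, master_seed=base_seed + i)
        result = run_study(run_cfg)
        s = result.summary()
        for soil_counts in s["enrichment_confusion"].values():
            for key in enr:
                enr[key] += soil_counts[key]
        for key in votu:
            votu[key] += s["votu_confusion"][key]
        c, t = result.soil_diff_accuracy()
        sd_correct += c
        sd_total += t
    return {
        "n_seeds": n_seeds,
        "enrichment": enr,
        "enrichment_sensitivity": enr["tp"] / max(enr["tp"] + enr["fn"], 1),
        "enrichment_fpr": enr["fp"] / max(enr["fp"] + enr["tn"], 1),
        "votu": votu,
        "votu_sensitivity": votu["tp"] / max(votu["tp"] + votu["fn"], 1),
        "votu_false_calls": votu["fp"],
        "soil_label_correct": sd_correct,
        "soil_label_total": sd_total,
    }


def library_stats(mappings: dict[str, MappingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library_id": sorted(mappings),
            "total_reads": [mappings[l].total_reads for l in sorted(mappings)],
            "unmapped": [mappings[l].unmapped for l in sorted(mappings)],
        }
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
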