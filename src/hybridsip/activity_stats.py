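"""Replicate-wise inference: 13C-enrichment tests, soil contrasts, heatmap.

Activity of a feature (a MAG-analog host group or a single vOTU contig) is
inferred from the relative proportion of high-buoyant-density (HBD) reads
mapping to it in the 13C versus the 12C treatment, across replicate
microcosms (n=3 per treatment): variances are first compared with a
two-sided F-test; a pooled-variance Student's t-test is used when variances
are homogeneous and Welch's t-test (Welch-Satterthwaite degrees of freedom)
otherwise. A feature is called enriched when the two-sided p-value is below
alpha AND the 13C mean exceeds the 12C mean. No multiple-testing correction
is applied by default; Benjamini-Hochberg is available by flag.

The same machinery drives the between-soil contrast on LBD proportions, and
``heatmap_matrix`` produces the ln(reads-per-kb) vOTU x library abundance
matrix, masking (never imputing) entries with zero counts or failing the
>=1x coverage / >=75% breadth detection filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import MappingResult
from .virus_screen import VOTUCall

DEFAULT_ALPHA = 0.05


def variance_check(x, y, alpha: float = DEFAULT_ALPHA) -> bool:
    """Two-sided F-test for homogeneity of variances.

    Returns True (homogeneous) iff p >= alpha. Identical samples are
    homogeneous by convention; one zero variance against a positive one is
    degenerate and treated as p = 0 (not homogeneous).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("variance_check requires >= 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return True
    if vx == 0.0 or vy == 0.0:
        return False
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p = 2.0 * min(stats.f.cdf(f, dfx, dfy), stats.f.sf(f, dfx, dfy))
    return bool(min(p, 1.0) >= alpha)


@dataclass
class ActivityCall:
    feature_id: str
    mean_12c: float
    mean_13c: float
    var_12c: float
    var_13c: float
    variance_homogeneous: bool
    test_used: str  # "student" | "welch"
    t_stat: float
    p_value: float
    enriched: bool


def _two_sample_t(x, y, equal_var: bool) -> tuple[float, float]:
    """t statistic and two-sided p for mean(y) - mean(x).

    Degenerate zero-variance cases: equal constants -> (0, 1); different
    constants -> (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if y.mean() == x.mean():
            return 0.0, 1.0
        return float(np.sign(y.mean() - x.mean()) * np.inf), 0.0
    res = stats.ttest_ind(y, x, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def enrichment_test(
    x_12c,
    x_13c,
    alpha: float = DEFAULT_ALPHA,
    variance_alpha: float = DEFAULT_ALPHA,
    feature_id: str = "",
    one_sided: bool = False,
) -> ActivityCall:
    """Per-feature 13C-enrichment test on replicate HBD read proportions.

    Two-sided test plus the direction requirement mean_13C > mean_12C by
    default; ``one_sided`` halves the p-value when the direction agrees.
    """
    x = np.asarray(x_12c, dtype=float)
    y = np.asarray(x_13c, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("enrichment_test requires >= 2 replicates per group")
    homogeneous = variance_check(x, y, alpha=variance_alpha)
    t, p = _two_sample_t(x, y, equal_var=homogeneous)
    if one_sided:
        p = p / 2.0 if t > 0 else 1.0 - p / 2.0
    greater = y.mean() > x.mean()
    return ActivityCall(
        feature_id=feature_id,
        mean_12c=float(x.mean()),
        mean_13c=float(y.mean()),
        var_12c=float(x.var(ddof=1)),
        var_13c=float(y.var(ddof=1)),
        variance_homogeneous=homogeneous,
        test_used="student" if homogeneous else "welch",
        t_stat=t,
        p_value=p,
        enriched=bool(p < alpha and greater),
    )


def enrichment_table(
    proportions_12c: pd.DataFrame,
    proportions_13c: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    variance_alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run enrichment_test for every feature (rows = features, cols = reps)."""
    features = list(proportions_12c.index)
    calls = [
        enrichment_test(
            proportions_12c.loc[f].to_numpy(),
            proportions_13c.loc[f].to_numpy(),
            alpha=alpha,
            variance_alpha=variance_alpha,
            feature_id=f,
        )
        for f in features
    ]
    df = pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "mean_12C": [c.mean_12c for c in calls],
            "mean_13C": [c.mean_13c for c in calls],
            "variance_homogeneous": [c.variance_homogeneous for c in calls],
            "test_used": [c.test_used for c in calls],
            "t_stat": [c.t_stat for c in calls],
            "p_value": [c.p_value for c in calls],
            "enriched": [c.enriched for c in calls],
        }
    )
    if bh_correct and len(df):
        df["p_adjusted"] = _benjamini_hochberg(df["p_value"].to_numpy())
        df["enriched"] = (df["p_adjusted"] < alpha) & (df["mean_13C"] > df["mean_12C"])
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def soil_differential(
    proportions_by_soil: dict[str, pd.DataFrame],
    alpha: float = DEFAULT_ALPHA,
    variance_alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Between-soil differential relative abundance on LBD proportions.

    Labels each feature with the soil it is significantly more abundant in,
    or 'ns'. Expects exactly two soils.
    """
    soils = sorted(proportions_by_soil)
    if len(soils) != 2:
        raise ValueError("soil_differential expects exactly two soils")
    a, b = soils
    dfa, dfb = proportions_by_soil[a], proportions_by_soil[b]
    features = [f for f in dfa.index if f in set(dfb.index)]
    rows = []
    for f in features:
        call = enrichment_test(
            dfa.loc[f].to_numpy(),
            dfb.loc[f].to_numpy(),
            alpha=alpha,
            variance_alpha=variance_alpha,
            feature_id=f,
        )
        if call.p_value < alpha:
            label = b if call.mean_13c > call.mean_12c else a
        else:
            label = "ns"
        rows.append(
            {
                "feature_id": f,
                f"mean_{a}": call.mean_12c,
                f"mean_{b}": call.mean_13c,
                "test_used": call.test_used,
                "t_stat": call.t_stat,
                "p_value": call.p_value,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HeatmapMatrix:
    """ln(reads per kb) per vOTU x library, with a detection mask."""

    values: pd.DataFrame  # NaN where masked
    mask: pd.DataFrame  # True = masked (no value)

    def to_frame(self) -> pd.DataFrame:
        long = self.values.stack(dropna=False).rename("ln_reads_per_kb").reset_index()
        long.columns = ["contig_id", "library_id", "ln_reads_per_kb"]
        long["masked"] = self.mask.stack().reset_index(drop=True)
        return long


def heatmap_matrix(
    mappings: dict[str, MappingResult],
    votus: list[VOTUCall],
    libraries: list[str] | None = None,
    min_coverage: float = 1.0,
    min_breadth: float = 0.75,
) -> HeatmapMatrix:
    """Relative abundance (reads per kb, ln transformed) of vOTUs.

    Entries with zero mapped reads or failing the coverage/breadth filters
    are masked, never imputed: ln(0) cannot appear.
    """
    lib_ids = libraries if libraries is not None else sorted(mappings)
    contig_ids = [v.contig_id for v in votus]
    lengths = {v.contig_id: v.length for v in votus}
    values = pd.DataFrame(np.nan, index=contig_ids, columns=lib_ids, dtype=float)
    mask = pd.DataFrame(True, index=contig_ids, columns=lib_ids, dtype=bool)
    for lib in lib_ids:
        mres = mappings[lib]
        for cid in contig_ids:
            count, depth, breadth = mres.per_contig(cid)
            if count > 0 and depth >= min_coverage and breadth >= min_breadth:
                values.loc[cid, lib] = np.log(count / (lengths[cid] / 1_000.0))
                mask.loc[cid, lib] = False
    values.index.name = "contig_id"
    mask.index.name = "contig_id"
    return HeatmapMatrix(values=values, mask=mask)
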