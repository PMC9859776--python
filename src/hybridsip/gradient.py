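"""Isopycnic CsCl gradient model: migration, banding, fractions, pools.

DNA's equilibrium buoyant density in a CsCl gradient rises linearly with GC
content (Schildkraut-type relation) and with heavy-isotope incorporation:

    BD = 1.660 + 0.098 * GC + 0.036 * (a - a0) / (1 - a0)   [g/ml]

where ``a`` is the atom fraction 13C of the DNA and ``a0`` = 0.011 is natural
abundance, so a fully labelled molecule is shifted by 0.036 g/ml. This is
what creates the co-migration problem the hybrid SIP design works around:
fully labelled low-GC (38 mol%) archaeal DNA lands at ~1.733 g/ml, on top of
*unlabelled* high-GC (>57 mol%) community DNA (>=1.716 g/ml), while the
unlabelled copy of the same low-GC genome stays down at ~1.697 g/ml where it
can be assembled cleanly from the low-buoyant-density (LBD) pool.

Each population's band is modelled as a Gaussian in density (diffusion
broadening), integrated over a discrete fraction scheme and renormalized
over the scheme's span so DNA mass is conserved exactly. Pools select whole
fractions by their midpoint: LBD < 1.699 g/ml, HBD > 1.719 g/ml.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .community import Scenario

logger = logging.getLogger(__name__)

BD_INTERCEPT = 1.660  # g/ml, buoyant density of GC=0 unlabelled DNA
BD_GC_SLOPE = 0.098  # g/ml per unit GC fraction
BD_FULL_LABEL_SHIFT = 0.036  # g/ml shift at 100 atom% 13C
NATURAL_13C = 0.011

LBD_MAX = 1.699  # g/ml; LBD pool = fractions with midpoint below this
HBD_MIN = 1.719  # g/ml; HBD pool = fractions with midpoint above this


def buoyant_density(
    gc: float,
    atom13c: float,
    intercept: float = BD_INTERCEPT,
    gc_slope: float = BD_GC_SLOPE,
    label_shift: float = BD_FULL_LABEL_SHIFT,
    natural: float = NATURAL_13C,
) -> float:
    """Equilibrium buoyant density (g/ml) of DNA with given GC and labelling.

    Strictly increasing in both arguments.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc {gc} outside [0, 1]")
    if not 0.0 <= atom13c <= 1.0:
        raise ValueError(f"atom13c {atom13c} outside [0, 1]")
    excess = (atom13c - natural) / (1.0 - natural)
    return intercept + gc_slope * gc + label_shift * excess


@dataclass(frozen=True)
class FractionScheme:
    """Contiguous half-open buoyant-density bins [e_i, e_{i+1})."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if len(e) < 9:
            raise ValueError("need >= 8 bins (>= 9 edges)")
        if not (np.diff(e) > 0).all():
            raise ValueError("edges must be strictly increasing")
        if e[0] > 1.66 or e[-1] < 1.78:
            raise ValueError("scheme must span [1.66, 1.78] g/ml")

    @classmethod
    def default(cls, n_bins: int = 24, lo: float = 1.66, hi: float = 1.78) -> "FractionScheme":
        """24 equal 0.005 g/ml fractions over [1.66, 1.78].

        With this width the 1.699/1.719 pooling cuts fall between fraction
        midpoints, so no fraction's pool membership is ambiguous.
        """
        return cls(tuple(np.round(np.linspace(lo, hi, n_bins + 1), 10)))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0


@dataclass(frozen=True)
class PoolSpec:
    """A pooled set of gradient fractions selected by midpoint density."""

    name: str  # "LBD" or "HBD"
    lbd_max: float = LBD_MAX
    hbd_min: float = HBD_MIN

    def __post_init__(self) -> None:
        if self.name not in ("LBD", "HBD"):
            raise ValueError("pool name must be 'LBD' or 'HBD'")
        if self.lbd_max >= self.hbd_min:
            raise ValueError("LBD threshold must be below HBD threshold")

    def selects(self, midpoints: np.ndarray) -> np.ndarray:
        mid = np.asarray(midpoints)
        if self.name == "LBD":
            return mid < self.lbd_max
        return mid > self.hbd_min


def band_masses(
    bd_mean: float,
    sigma: float,
    total_mass: float,
    scheme: FractionScheme,
) -> np.ndarray:
    """Gaussian band integrated over fraction bins; conserves total_mass.

    Mass falling outside the scheme's span is renormalized into the span
    (equivalently: the band is truncated to the gradient), so the returned
    vector always sums to total_mass.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    edges = np.asarray(scheme.edges)
    if bd_mean < edges[0] - 5 * sigma or bd_mean > edges[-1] + 5 * sigma:
        logger.warning(
            "band mean %.4f g/ml lies >5 sigma outside the fraction scheme "
            "[%.3f, %.3f]; mass piles into the edge bin",
            bd_mean,
            edges[0],
            edges[-1],
        )
    cdf = norm.cdf(edges, loc=bd_mean, scale=sigma)
    raw = np.diff(cdf)
    span = cdf[-1] - cdf[0]
    if span <= 0:  # entire band numerically outside the span: edge bin
        out = np.zeros(scheme.n_bins)
        out[0 if bd_mean < edges[0] else -1] = total_mass
        return out
    return raw * (total_mass / span)


@dataclass
class GradientProfile:
    """Per-population DNA mass across fractions for one gradient (replicate)."""

    scheme: FractionScheme
    pop_ids: list[str]
    mass: np.ndarray  # (n_pops, n_fractions)
    replicate_id: int
    treatment: str
    soil: str
    input_mass: np.ndarray = field(default=None)  # per-population totals

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (len(self.pop_ids), self.scheme.n_bins):
            raise ValueError("mass matrix shape mismatch")
        if (self.mass < 0).any():
            raise ValueError("negative mass")
        if self.input_mass is None:
            self.input_mass = self.mass.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.mass.T, index=self.scheme.midpoints, columns=self.pop_ids
        )
        df.index.name = "bd_midpoint"
        return df


def simulate_gradient(
    scenario: Scenario,
    soil: str,
    treatment: str,
    replicate_id: int,
    scheme: FractionScheme | None = None,
    sigma: float = 0.003,
    jitter_sd: float = 0.0005,
    seed: int = 0,
    bd_params: dict | None = None,
) -> GradientProfile:
    """Band every population of one soil in one gradient.

    Replicate-to-replicate variation (the error bars one sees when plotting
    fraction profiles from independent gradients) enters as
    Normal(0, jitter_sd) noise on each population's band centre, seeded per
    (soil, treatment, replicate).
    """
    scheme = scheme or FractionScheme.default()
    rng = np.random.default_rng(seed)
    pops = [p for p in scenario.populations if p.abundance.get(soil, 0.0) > 0.0]
    pop_ids = [p.pop_id for p in pops]
    mass = np.zeros((len(pops), scheme.n_bins))
    params = bd_params or {}
    for i, pop in enumerate(pops):
        genome = scenario.genomes[pop.pop_id]
        bd = buoyant_density(genome.realized_gc, pop.atom_fraction(treatment), **params)
        bd += float(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 0.0
        mass[i] = band_masses(bd, sigma, pop.abundance[soil], scheme)
    return GradientProfile(
        scheme=scheme,
        pop_ids=pop_ids,
        mass=mass,
        replicate_id=replicate_id,
        treatment=treatment,
        soil=soil,
    )


def marker_profile(profile: GradientProfile, marker_populations: list[str]) -> np.ndarray:
    """Relative-abundance profile of a marker-gene group across fractions.

    Sums the selected populations' mass per fraction and normalizes over
    fractions — the analog of plotting 16S rRNA (whole community) or amoA
    (AOA) gene relative abundance per fraction.
    """
    if not marker_populations:
        raise ValueError("marker population subset must be non-empty")
    idx = [profile.pop_ids.index(p) for p in marker_populations]
    total = profile.mass[idx].sum(axis=0)
    s = total.sum()
    if s <= 0:
        raise ValueError("selected populations carry no mass in this gradient")
    return total / s


def pool_fractions(profile: GradientProfile, pool: PoolSpec) -> pd.Series:
    """Per-population DNA mass pooled over the fractions a pool selects.

    Populations with zero pooled mass are retained with mass 0.
    """
    sel = pool.selects(profile.scheme.midpoints)
    pooled = profile.mass[:, sel].sum(axis=1)
    return pd.Series(pooled, index=profile.pop_ids, name=pool.name)
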