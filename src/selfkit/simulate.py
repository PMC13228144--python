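"""Synthetic genotype data for partially selfing, structured populations.

The generator emulates a genotyping-by-sequencing study of an invasive,
predominantly selfing plant: a handful of diverged lineages (Balding-Nichols
allele-frequency divergence from a common ancestral pool), populations that
reproduce by mixed mating (each individual carries a latent count ``G`` of
consecutive selfing generations in its ancestry, geometric with parameter
``s``), rare inter-lineage hybrids of known class and age, and
individual-level missing data.

The shared-``G`` construction is the scientific heart: because one ``G`` is
drawn per *individual* and applied to every locus, heterozygosity is
correlated across loci within individuals (identity disequilibrium), which
is the signal the multilocus selfing-rate estimator in
:mod:`selfkit.selfing` reads. Redrawing ``G`` per locus would produce the
same heterozygote deficit but zero identity disequilibrium; that variant
exists only as a test fixture (:func:`simulate_locus_independent_population`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING, GenotypeMatrix

#: Residual heterozygosity 2^-50 is below any representable signal; capping
#: the selfing-ancestry depth here keeps s = 1 finite.
G_CAP = 50

#: Allele frequencies are clipped into [EPS, 1 - EPS].
EPS = 1e-6

HYBRID_CLASSES = ("F1", "F2", "F1xA", "F1xB", "F1AxA", "F1AxB", "F1BxB", "F1BxA")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LineageSpec:
    label: str
    fst: float  # Balding-Nichols divergence from the ancestral pool, in [0, 1)


@dataclass
class PopulationSpec:
    label: str
    lineage: str
    n: int
    selfing_rate: float


@dataclass
class AdmixtureEventSpec:
    """A planted batch of hybrids between two lineages.

    ``selfing_generations`` is the number of selfing generations applied
    after the terminal cross: 0 for recent hybrids, >= 4 for historical ones.
    """

    parent_a: str
    parent_b: str
    hybrid_class: str
    n: int
    selfing_generations: int
    host_population: str


@dataclass
class MissingnessSpec:
    mean_rate: float = 0.0
    concentration: float = 1.5


@dataclass
class ScenarioConfig:
    n_loci: int
    lineages: list[LineageSpec]
    populations: list[PopulationSpec]
    seed: int
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    admixture_events: list[AdmixtureEventSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        labels = [l.label for l in self.lineages]
        if len(set(labels)) != len(labels):
            raise ValueError("lineage labels must be unique")
        for l in self.lineages:
            if not 0.0 <= l.fst < 1.0:
                raise ValueError(f"lineage {l.label}: fst must be in [0, 1)")
        for p in self.populations:
            if p.n < 1:
                raise ValueError(f"population {p.label}: n must be >= 1")
            if not 0.0 <= p.selfing_rate <= 1.0:
                raise ValueError(f"population {p.label}: selfing rate out of range")
            if p.lineage not in labels:
                raise ValueError(f"population {p.label}: unknown lineage {p.lineage}")
        for e in self.admixture_events:
            if e.hybrid_class not in HYBRID_CLASSES:
                raise ValueError(f"unknown hybrid class {e.hybrid_class!r}")
            if e.selfing_generations < 0:
                raise ValueError("selfing_generations must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["lineages"] = [LineageSpec(**d) for d in raw["lineages"]]
        raw["populations"] = [PopulationSpec(**d) for d in raw["populations"]]
        raw["missingness"] = MissingnessSpec(**raw.get("missingness", {}))
        raw["admixture_events"] = [AdmixtureEventSpec(**d)
                                   for d in raw.get("admixture_events", [])]
        return cls(**raw)


@dataclass
class AlleleFrequencyTable:
    """Latent per-lineage allele frequencies behind the observed genotypes."""

    lineage_labels: list[str]
    frequencies: np.ndarray  # (n_lineages, n_loci), clipped to [EPS, 1-EPS]
    ancestral: np.ndarray

    def for_lineage(self, label: str) -> np.ndarray:
        return self.frequencies[self.lineage_labels.index(label)]


# ---------------------------------------------------------------------------
# Core operators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_lineage_frequencies(config: ScenarioConfig,
                                 seed=None) -> AlleleFrequencyTable:
    """Draw ancestral and per-lineage allele frequencies.

    Ancestral frequencies are Uniform(ancestral_low, ancestral_high); each
    lineage's frequencies follow the Balding-Nichols law
    ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` around the ancestral ``p0`` with its
    divergence parameter ``F`` (star-shaped divergence). ``F = 0`` copies the
    ancestral frequencies exactly.
    """
    rng = _rng(config.seed if seed is None else seed)
    p0 = rng.uniform(config.ancestral_low, config.ancestral_high, size=config.n_loci)
    freqs = np.empty((len(config.lineages), config.n_loci))
    for k, lin in enumerate(config.lineages):
        if lin.fst == 0.0:
            freqs[k] = p0
        else:
            c = (1.0 - lin.fst) / lin.fst
            freqs[k] = rng.beta(p0 * c, (1.0 - p0) * c)
    freqs = np.clip(freqs, EPS, 1.0 - EPS)
    return AlleleFrequencyTable([l.label for l in config.lineages], freqs, p0)


def draw_selfing_depths(s: float, n: int, rng) -> np.ndarray:
    """Geometric selfing-ancestry depths: P(G = g) = (1 - s) s^g, capped at G_CAP."""
    if s >= 1.0:
        warnings.warn("s = 1: all selfing-ancestry depths set to the cap")
        return np.full(n, G_CAP, dtype=int)
    g = rng.geometric(1.0 - s, size=n) - 1
    return np.minimum(g, G_CAP)


def simulate_mixed_mating_population(freqs: np.ndarray, s: float, n: int,
                                     seed) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` genotypes under mixed mating at equilibrium.

    One selfing-ancestry depth ``G`` is drawn per individual (shared across
    loci). Per locus the first allele is Bernoulli(p); with probability
    ``1 - (1/2)^G`` the second allele is identical by descent, otherwise an
    independent Bernoulli(p) draw. Returns ``(genotypes, G)``.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    p = np.asarray(freqs, dtype=float)
    L = p.size
    G = draw_selfing_depths(s, n, rng)
    a = (rng.random((n, L)) < p).astype(np.int8)
    ibd = rng.random((n, L)) < (1.0 - 0.5 ** G)[:, None]
    b_ind = (rng.random((n, L)) < p).astype(np.int8)
    b = np.where(ibd, a, b_ind)
    return (a + b).astype(np.int8), G


def simulate_locus_independent_population(freqs: np.ndarray, s: float, n: int,
                                          seed) -> np.ndarray:
    """Test fixture: redraw the selfing depth per locus instead of per individual.

    Produces the same marginal heterozygote deficit (F = s/(2-s)) but zero
    identity disequilibrium (g2 = 0); used to verify that the estimator reads
    cross-locus structure, not the deficit itself.
    """
    rng = _rng(seed)
    p = np.asarray(freqs, dtype=float)
    L = p.size
    G = np.minimum(rng.geometric(1.0 - s, size=(n, L)) - 1, G_CAP) if s < 1.0 \
        else np.full((n, L), G_CAP)
    a = (rng.random((n, L)) < p).astype(np.int8)
    ibd = rng.random((n, L)) < (1.0 - 0.5 ** G)
    b = np.where(ibd, a, (rng.random((n, L)) < p).astype(np.int8))
    return (a + b).astype(np.int8)


def self_offspring(genotypes: np.ndarray, generations: int, seed) -> np.ndarray:
    """Apply ``generations`` rounds of Mendelian self-fertilization.

    Homozygous and missing entries are invariant. A heterozygous locus
    survives ``g`` rounds heterozygous with probability ``(1/2)^g`` and
    otherwise fixes to 0 or 2 with equal probability (the exact g-round
    distribution, sampled in one shot). Accepts a single row or a matrix.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    geno = np.asarray(genotypes, dtype=np.int8)
    out = geno.copy()
    if generations == 0:
        return out
    rng = _rng(seed)
    het = geno == 1
    survive = rng.random(geno.shape) < 0.5 ** generations
    fix_high = rng.random(geno.shape) < 0.5
    resolved = np.where(fix_high, 2, 0).astype(np.int8)
    out[het & ~survive] = resolved[het & ~survive]
    return out


def apply_missingness(gm: GenotypeMatrix, mean_rate: float,
                      concentration: float = 1.5, seed=None) -> GenotypeMatrix:
    """Mask entries with per-individual Beta-distributed missing rates.

    Rates are Beta(mean*c, (1-mean)*c); with ``c`` around 1.5 the rate
    distribution is right-skewed (median well below the mean), as in
    reduced-representation sequencing panels. ``mean_rate = 0`` is the
    identity.
    """
    if not 0.0 <= mean_rate < 1.0:
        raise ValueError("mean_rate must be in [0, 1)")
    if mean_rate == 0.0:
        return GenotypeMatrix(gm.genotypes.copy(), gm.sample_ids,
                              gm.population_labels, gm.locus_ids)
    rng = _rng(seed)
    rates = rng.beta(mean_rate * concentration,
                     (1.0 - mean_rate) * concentration, size=gm.n_individuals)
    mask = rng.random(gm.genotypes.shape) < rates[:, None]
    geno = gm.genotypes.copy()
    geno[mask] = MISSING
    return GenotypeMatrix(geno, gm.sample_ids, gm.population_labels, gm.locus_ids)


# ---------------------------------------------------------------------------
# Hybrid construction primitives (shared with selfkit.hybrids)
# ---------------------------------------------------------------------------

def _gametes(geno: np.ndarray, rng) -> np.ndarray:
    """One gamete per locus from each genotype row: het loci segregate 50/50."""
    allele = (geno // 2).astype(np.int8)  # 0 -> 0, 2 -> 1
    het = geno == 1
    rand = (rng.random(geno.shape) < 0.5).astype(np.int8)
    return np.where(het, rand, allele)


def simulate_cross(pool_a: np.ndarray, pool_b: np.ndarray, hybrid_class: str,
                   n: int, seed) -> np.ndarray:
    """Genealogical simulation of a hybrid class from two parental allele pools.

    ``pool_a``/``pool_b`` are per-locus allele frequencies. F1 draws one
    allele from each pool; F2 crosses two independent F1s; first-generation
    backcrosses (F1xA, F1xB) cross an F1 gamete with a fresh pool allele;
    second-generation backcrosses (F1AxA, F1AxB, F1BxB, F1BxA) do the same
    starting from a simulated first-generation backcross.
    """
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {hybrid_class!r}; "
                         f"expected one of {HYBRID_CLASSES}")
    rng = _rng(seed)
    pa = np.asarray(pool_a, dtype=float)
    pb = np.asarray(pool_b, dtype=float)
    L = pa.size

    def pool_allele(p):
        return (rng.random((n, L)) < p).astype(np.int8)

    def f1():
        return pool_allele(pa) + pool_allele(pb)

    if hybrid_class == "F1":
        return f1().astype(np.int8)
    if hybrid_class == "F2":
        return (_gametes(f1(), rng) + _gametes(f1(), rng)).astype(np.int8)
    if hybrid_class == "F1xA":
        return (_gametes(f1(), rng) + pool_allele(pa)).astype(np.int8)
    if hybrid_class == "F1xB":
        return (_gametes(f1(), rng) + pool_allele(pb)).astype(np.int8)
    first = {"F1AxA": "F1xA", "F1AxB": "F1xA",
             "F1BxB": "F1xB", "F1BxA": "F1xB"}[hybrid_class]
    parent = simulate_cross(pa, pb, first, n, rng)
    other = pa if hybrid_class in ("F1AxA", "F1BxA") else pb
    return (_gametes(parent, rng) + pool_allele(other)).astype(np.int8)


def expected_ancestry_a(hybrid_class: str) -> float:
    """Expected pool-A ancestry fraction of a hybrid class."""
    return {"F1": 0.5, "F2": 0.5, "F1xA": 0.75, "F1xB": 0.25,
            "F1AxA": 0.875, "F1AxB": 0.375, "F1BxB": 0.125,
            "F1BxA": 0.625}[hybrid_class]


# ---------------------------------------------------------------------------
# Scenario engine and the study-scale preset
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig
                      ) -> tuple[GenotypeMatrix, pd.DataFrame, AlleleFrequencyTable]:
    """Run a full scenario: frequencies, populations, hybrids, missingness.

    Returns the genotype matrix, a truth table (one row per individual:
    population, lineage or hybrid parents, category, selfing-ancestry depth
    ``G``, post-admixture selfing generations ``g_post``, expected pool-A
    ancestry fraction), and the latent allele-frequency table. Everything is
    reproducible bit-for-bit from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    freqs = simulate_lineage_frequencies(config, seed=rng)
    rows: list[np.ndarray] = []
    truth: list[dict] = []
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    for pop in config.populations:
        p = freqs.for_lineage(pop.lineage)
        geno, G = simulate_mixed_mating_population(p, pop.selfing_rate, pop.n, rng)
        rows.append(geno)
        for i in range(pop.n):
            sid = f"{pop.label}_{i + 1:02d}"
            sample_ids.append(sid)
            pop_labels.append(pop.label)
            truth.append(dict(sample_id=sid, population=pop.label,
                              lineage=pop.lineage, category="pure",
                              hybrid_class="", parents="",
                              selfing_depth=int(G[i]), g_post=0,
                              ancestry_a=np.nan, true_selfing_rate=pop.selfing_rate))
    for k, ev in enumerate(config.admixture_events):
        pa = freqs.for_lineage(ev.parent_a)
        pb = freqs.for_lineage(ev.parent_b)
        geno = simulate_cross(pa, pb, ev.hybrid_class, ev.n, rng)
        if ev.selfing_generations > 0:
            geno = self_offspring(geno, ev.selfing_generations, rng)
        rows.append(geno)
        category = "historical_hybrid" if ev.selfing_generations >= 4 else "recent_hybrid"
        for i in range(ev.n):
            sid = f"{ev.host_population}_hyb{k + 1}_{i + 1:02d}"
            sample_ids.append(sid)
            pop_labels.append(ev.host_population)
            truth.append(dict(sample_id=sid, population=ev.host_population,
                              lineage="", category=category,
                              hybrid_class=ev.hybrid_class,
                              parents=f"{ev.parent_a}x{ev.parent_b}",
                              selfing_depth=0, g_post=ev.selfing_generations,
                              ancestry_a=expected_ancestry_a(ev.hybrid_class),
                              true_selfing_rate=np.nan))
    geno = np.vstack(rows)
    locus_ids = [f"L{j + 1:05d}" for j in range(config.n_loci)]
    gm = GenotypeMatrix(geno, sample_ids, pop_labels, locus_ids)
    if config.missingness.mean_rate > 0:
        gm = apply_missingness(gm, config.missingness.mean_rate,
                               config.missingness.concentration, rng)
    return gm, pd.DataFrame(truth), freqs


# Study-scale preset. Population sample sizes and per-population selfing
# rates mirror the sampling design of the motivating survey: 26 invasive
# European populations in three lineages, four native South African
# populations (one of them a diverse, mostly outcrossing population that
# serves as the high-diversity hybrid parent), ~6,000 unlinked SNPs, and a
# right-skewed ~6.5% mean individual missingness. One invasive population
# (PT-CMAR analogue, "inv_PT2") is composed of historical hybrids plus one
# recent backcross; eight recent hybrids with the native diverse lineage are
# scattered across other invasive populations.
_PRESET_POPULATIONS: list[tuple[str, str, int, float]] = [
    # label, lineage, n, selfing rate
    ("inv_SU1", "RED", 8, 0.829),
    ("inv_SU2", "RED", 8, 0.722),
    ("inv_SU3", "RED", 18, 0.905),
    ("inv_DE1", "RED", 9, 0.940),
    ("inv_NL1", "RED", 9, 0.887),
    ("inv_PT1", "RED", 10, 0.792),
    ("inv_ES1", "RED", 16, 0.352),
    ("inv_ES2", "RED", 8, 0.758),
    ("inv_ES3", "RED", 9, 0.233),
    ("inv_ES4", "RED", 8, 0.662),
    ("inv_ES5", "RED", 9, 0.693),
    ("inv_ES6", "RED", 7, 0.567),
    ("inv_ES7", "RED", 9, 0.725),
    ("inv_UK6", "RED", 9, 0.382),
    ("inv_ES8", "RED", 1, 0.7),
    ("inv_UK1", "ORANGE", 18, 0.472),
    ("inv_UK2", "ORANGE", 9, 0.938),
    ("inv_UK3", "ORANGE", 9, 0.619),
    ("inv_UK4", "ORANGE", 9, 0.536),
    ("inv_UK5", "ORANGE", 9, 0.760),
    ("inv_NL2", "ORANGE", 9, 0.880),
    ("inv_UK7", "ORANGE", 1, 0.7),
    ("inv_UK8", "ORANGE", 1, 0.7),
    ("inv_SU4", "YELLOW", 9, 0.777),
    ("inv_NL3", "YELLOW", 9, 0.364),
    # PT-CMAR analogue: listed with n=0 pure individuals; its members are the
    # planted historical hybrids below.
    ("nat_CAPE", "NAT_CAPE", 9, 0.652),
    ("nat_CLIF", "NAT_CLIF", 10, 0.985),
    ("nat_GANS", "NAT_GANS", 8, 0.730),
    ("nat_AGUL", "BLUE", 9, 0.169),
]

_PRESET_LINEAGES = [
    ("RED", 0.45), ("ORANGE", 0.45), ("YELLOW", 0.45),
    ("NAT_CAPE", 0.35), ("NAT_CLIF", 0.35), ("NAT_GANS", 0.35),
    ("BLUE", 0.08),
]

_PRESET_EVENTS: list[tuple[str, str, str, int, int, str]] = [
    # parent_a, parent_b, class, n, selfing generations, host population
    # Historical RED x YELLOW hybrids forming the "inv_PT2" population,
    # plus one recent backcross there (PT-CMAR analogue).
    ("RED", "YELLOW", "F1", 2, 4, "inv_PT2"),
    ("RED", "YELLOW", "F1", 2, 5, "inv_PT2"),
    ("RED", "YELLOW", "F1", 2, 6, "inv_PT2"),
    ("RED", "YELLOW", "F1", 2, 8, "inv_PT2"),
    ("RED", "YELLOW", "F1xA", 1, 0, "inv_PT2"),
    # Recent hybrids with the diverse native lineage, scattered.
    ("RED", "BLUE", "F1", 2, 0, "inv_ES1"),
    ("RED", "BLUE", "F1", 2, 0, "inv_SU3"),
    ("RED", "BLUE", "F1xA", 2, 0, "inv_NL1"),
    ("RED", "BLUE", "F1xA", 2, 0, "inv_PT1"),
]

PRESETS = ("paper_like",)


def study_config(preset: str = "paper_like", seed: int = 0,
                 n_loci: int = 6000) -> ScenarioConfig:
    """Build the ScenarioConfig for a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {PRESETS}")
    return ScenarioConfig(
        n_loci=n_loci,
        lineages=[LineageSpec(a, b) for a, b in _PRESET_LINEAGES],
        populations=[PopulationSpec(*row) for row in _PRESET_POPULATIONS],
        # concentration 4.3 puts the Beta median near 1.6% at mean 6.5%,
        # the right-skewed per-individual profile of the emulated survey
        missingness=MissingnessSpec(mean_rate=0.065, concentration=4.3),
        admixture_events=[AdmixtureEventSpec(*row) for row in _PRESET_EVENTS],
        seed=seed,
    )


def simulate_study(preset: str = "paper_like", seed: int = 0, n_loci: int = 6000
                   ) -> tuple[GenotypeMatrix, pd.DataFrame, ScenarioConfig]:
    """Simulate the full study-scale scenario; returns (matrix, truth, config)."""
    config = study_config(preset, seed=seed, n_loci=n_loci)
    gm, truth, _ = simulate_scenario(config)
    return gm, truth, config
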