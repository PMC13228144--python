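"""Hybrid-class simulation and recency-of-admixture classification.

Given two parental lineages, genotypes of F1, F2 and first/second-generation
backcross classes are simulated genealogically from the parental allele
pools, and every simulated individual is placed on the (q, H_O) plane:
supervised ancestry coefficient q against observed heterozygosity. A recent
hybrid sits inside the heterozygosity envelope spanned by the simulated
classes with comparable ancestry; generations of selfing after an old
hybridization event halve heterozygosity each generation without moving q,
pushing historical hybrids below that envelope. The classifier
operationalizes the visual comparison with an adaptive-window percentile
envelope: for each empirical point, simulated individuals with |q_sim - q|
within a window are pooled (window doubled until enough matches), and the
point is called *recent* if its H_O reaches the lower band percentile,
*historical* if it falls below, *unresolved* if the window never collects
enough matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import supervised_ancestry
from .genotypes import MISSING, GenotypeMatrix, observed_heterozygosity
from .simulate import HYBRID_CLASSES, expected_ancestry_a, self_offspring, simulate_cross


@dataclass
class HybridClassSet:
    """Simulated hybrid genotypes with their (q, H_O) coordinates.

    ``table`` columns: class, sample, q, h_obs. ``q`` is the supervised
    pool-A ancestry coefficient computed with the same estimator and pools
    used for empirical individuals, keeping classification internally
    consistent.
    """

    genotypes: np.ndarray
    classes: np.ndarray  # class label per simulated individual
    q: np.ndarray
    h_obs: np.ndarray
    pool_a: np.ndarray
    pool_b: np.ndarray
    n_per_class: int
    seed: int | None

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.classes,
            "sample": [f"sim_{c}_{i}" for i, c in enumerate(self.classes)],
            "q": self.q,
            "h_obs": self.h_obs,
        })


@dataclass
class RecencyCall:
    sample_id: str
    q: float
    h_obs: float
    envelope_lo: float
    envelope_hi: float
    n_matched_sims: int
    call: str  # recent | historical | unresolved


def build_parent_pools(gm: GenotypeMatrix, Q: np.ndarray,
                       threshold: float = 0.999,
                       cluster_a: int = 0, cluster_b: int = 1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus parental allele frequencies from pure individuals.

    Individuals with cluster membership >= ``threshold`` form each pool
    (complete-case frequencies per locus). Each pool must contain at least 3
    individuals; otherwise the offending cluster is named in the error.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != gm.n_individuals:
        raise ValueError("Q rows must match individuals")
    pools = []
    for k in (cluster_a, cluster_b):
        idx = np.flatnonzero(Q[:, k] >= threshold)
        if len(idx) < 3:
            raise ValueError(
                f"cluster {k}: only {len(idx)} individuals at q >= {threshold}; "
                "need at least 3 for a parental pool")
        pools.append(gm.take_individuals(idx).allele_frequencies())
    return pools[0], pools[1]


def simulate_hybrid_classes(pool_a: np.ndarray, pool_b: np.ndarray,
                            n_per_class: int = 25,
                            classes: tuple[str, ...] = HYBRID_CLASSES,
                            seed=None) -> HybridClassSet:
    """Simulate ``n_per_class`` individuals for each requested hybrid class.

    Pools must be frequency vectors on identical loci. q and H_O are
    computed for every simulated individual (q via supervised ancestry
    against the same pools).
    """
    pa = np.asarray(pool_a, dtype=float)
    pb = np.asarray(pool_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("pools must be on identical loci")
    for c in classes:
        if c not in HYBRID_CLASSES:
            raise ValueError(f"unknown hybrid class {c!r}")
    rng = np.random.default_rng(seed)
    genos, labels = [], []
    for c in classes:
        genos.append(simulate_cross(pa, pb, c, n_per_class, rng))
        labels.extend([c] * n_per_class)
    geno = np.vstack(genos)
    gm = GenotypeMatrix(geno,
                        [f"sim_{i}" for i in range(geno.shape[0])],
                        ["sim"] * geno.shape[0],
                        [f"L{j}" for j in range(geno.shape[1])])
    q = supervised_ancestry(gm, pa, pb)
    h = observed_heterozygosity(gm)
    return HybridClassSet(geno, np.asarray(labels), q, h, pa, pb,
                          n_per_class, seed if isinstance(seed, int) else None)


def selfing_decay(hcs: HybridClassSet, generations: int, seed=None
                  ) -> HybridClassSet:
    """Apply ``generations`` of selfing to every simulated individual.

    Heterozygosity decays by (1/2) per generation in expectation; the
    ancestry coefficient q is unchanged in expectation.
    """
    rng = np.random.default_rng(seed)
    geno = self_offspring(hcs.genotypes, generations, rng)
    gm = GenotypeMatrix(geno,
                        [f"sim_{i}" for i in range(geno.shape[0])],
                        ["sim"] * geno.shape[0],
                        [f"L{j}" for j in range(geno.shape[1])])
    q = supervised_ancestry(gm, hcs.pool_a, hcs.pool_b)
    h = observed_heterozygosity(gm)
    return HybridClassSet(geno, hcs.classes.copy(), q, h, hcs.pool_a,
                          hcs.pool_b, hcs.n_per_class, hcs.seed)


def classify_recency(points: pd.DataFrame, sims: HybridClassSet,
                     q_window: float = 0.05,
                     band: tuple[float, float] = (2.5, 97.5),
                     min_matches: int = 20) -> list[RecencyCall]:
    """Call each empirical (q, H_O) point recent, historical, or unresolved.

    ``points`` needs columns ``sample_id, q, h_obs``. For each point,
    simulated individuals of all classes with ``|q_sim - q| <= window`` are
    pooled, the window doubling from ``q_window`` until ``min_matches``
    matches are found or the window reaches 0.5. The envelope is the
    ``band`` percentiles of the matched simulated H_O values; the call is
    *recent* when the point's H_O is at or above the lower edge,
    *historical* below it, and *unresolved* when matches never reach
    ``min_matches``.
    """
    if len(sims.q) == 0:
        raise ValueError("sims must be non-empty")
    calls: list[RecencyCall] = []
    sim_q = np.asarray(sims.q)
    sim_h = np.asarray(sims.h_obs)
    for _, row in points.iterrows():
        q, h = float(row["q"]), float(row["h_obs"])
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"{row['sample_id']}: q outside [0, 1]")
        window = q_window
        matched = np.abs(sim_q - q) <= window
        while matched.sum() < min_matches and window < 0.5:
            window = min(window * 2.0, 0.5)
            matched = np.abs(sim_q - q) <= window
        n_match = int(matched.sum())
        if n_match < min_matches:
            calls.append(RecencyCall(str(row["sample_id"]), q, h,
                                     np.nan, np.nan, n_match, "unresolved"))
            continue
        lo, hi = np.percentile(sim_h[matched], band)
        call = "recent" if h >= lo else "historical"
        calls.append(RecencyCall(str(row["sample_id"]), q, h,
                                 float(lo), float(hi), n_match, call))
    return calls


def recency_calls_frame(calls: list[RecencyCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def analyze_pair(gm: GenotypeMatrix, pops_a: list[str], pops_b: list[str],
                 extra_pops: list[str] | None = None, n_per_class: int = 25,
                 q_window: float = 0.05, band: tuple[float, float] = (2.5, 97.5),
                 min_matches: int = 20, purity_threshold: float = 0.999,
                 candidate_threshold: float = 0.99,
                 subsample_loci: int | None = None, n_restarts: int = 3,
                 max_iter: int = 500, seed=None
                 ) -> tuple[pd.DataFrame, HybridClassSet]:
    """Full recency analysis for one parental-lineage pair.

    Runs a two-cluster admixture fit restricted to the populations of the
    two parental lineages (plus ``extra_pops``, e.g. populations of unknown
    ancestry), builds parental pools from individuals pure at
    ``purity_threshold``, simulates the hybrid classes, and classifies every
    individual whose maximum cluster membership is below
    ``candidate_threshold``. Returns the calls (one row per candidate, with
    the candidate's supervised q and H_O) and the simulated class set.
    """
    from .ancestry import admixture_em

    rng = np.random.default_rng(seed)
    pops = list(pops_a) + list(pops_b) + list(extra_pops or [])
    idx = [i for i, p in enumerate(gm.population_labels) if p in pops]
    if not idx:
        raise ValueError("no individuals in the requested populations")
    sub = gm.take_individuals(np.asarray(idx))
    if subsample_loci and sub.n_loci > subsample_loci:
        keep = np.sort(rng.choice(sub.n_loci, subsample_loci, replace=False))
        sub = sub.take_loci(keep)
    res = admixture_em(sub, K=2, n_restarts=n_restarts, max_iter=max_iter,
                       seed=int(rng.integers(2**31)))
    in_a = np.isin(sub.population_labels, list(pops_a))
    cluster_a = int(np.argmax(res.Q[in_a].mean(axis=0)))
    pool_a, pool_b = build_parent_pools(sub, res.Q, purity_threshold,
                                        cluster_a, 1 - cluster_a)
    sims = simulate_hybrid_classes(pool_a, pool_b, n_per_class,
                                   seed=int(rng.integers(2**31)))
    cand = np.flatnonzero(res.Q.max(axis=1) < candidate_threshold)
    if len(cand) == 0:
        return recency_calls_frame([]), sims
    cand_gm = sub.take_individuals(cand)
    pts = pd.DataFrame({
        "sample_id": [sub.sample_ids[i] for i in cand],
        "q": supervised_ancestry(cand_gm, pool_a, pool_b),
        "h_obs": observed_heterozygosity(cand_gm),
    })
    calls = recency_calls_frame(
        classify_recency(pts, sims, q_window, band, min_matches))
    return calls, sims
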