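"""Orchestration: the full analysis sequence over simulated or user data.

``run_pipeline`` strings the package's stages together in the order a
population-genomic survey of a selfing invader would run them: locus
filtering, a within-population kinship screen for clones and close
relatives, diversity summaries, per-population and per-lineage selfing-rate
estimation, admixture-model clustering across a sweep of K with the Evanno
delta-K table, parental-pool construction, hybrid-class simulation with
recency-of-admixture calls, folded SFS export per cluster, and
divergence-time conversion. Every stage is seeded from the single config
seed and all tabular outputs are TSV, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import (admixture_degree, admixture_em, evanno_delta_k,
                       pca_mean_impute)
from .genotypes import (GenotypeMatrix, diversity_summary, filter_loci,
                        folded_sfs, king_kinship, observed_heterozygosity,
                        read_genotypes, write_sfs)
from .hybrids import analyze_pair
from .selfing import estimate_selfing
from .simulate import simulate_study

log = logging.getLogger("selfkit.pipeline")

#: Standard KING kinship bins: phi > 0.45 duplicate/clone; first-degree
#: relatives around 0.25 fall in [0.177, 0.354); the screen flags phi >= 0.177.
CLONE_PHI = 0.45
FIRST_DEGREE_LO = 0.177
FIRST_DEGREE_HI = 0.354


@dataclass
class DivergenceTimeResult:
    """Conversion between coalescent divergence and absolute time: tau = 2 mu t."""

    tau: float
    mu: float
    generation_time: float
    t_years: float


def divergence_time(tau: float, mu: float = 7.0e-9,
                    generation_time: float = 1.0) -> DivergenceTimeResult:
    """Convert divergence tau (substitutions/site) to years: t = g * tau / (2 mu).

    Defaults are a plant-style per-site per-generation mutation rate of
    7.0e-9 and a one-year generation time.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if tau < 0 or generation_time < 0:
        raise ValueError("tau and generation_time must be non-negative")
    return DivergenceTimeResult(tau, mu, generation_time,
                                generation_time * tau / (2.0 * mu))


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results/pipeline",
    "input": {"preset": "paper_like", "n_loci": 6000},
    "filter": {"max_missing_frac": 0.1, "min_maf": 0.0},
    "kinship": {"within_population": True},
    "selfing": {"max_loci": 1000, "n_perm": 1000, "n_boot": 500},
    "ancestry": {"k_values": [1, 2, 3, 4, 5], "replicates": 3, "k_main": None,
                 "subsample_loci": 2000, "n_restarts": 3, "max_iter": 500,
                 "purity_threshold": 0.999, "pca_components": 2},
    "hybrids": {"pairs": [], "n_per_class": 25, "q_window": 0.05,
                "band": [2.5, 97.5], "min_matches": 20},
    "sfs": {"projection_n": None},
    "divergence": {"mu": 7.0e-9, "generation_time": 1.0, "tau_values": []},
}


@dataclass
class PipelineReport:
    """Per-stage outputs plus run metadata; every table is also on disk."""

    config: dict
    config_hash: str
    outdir: Path
    diversity_individual: pd.DataFrame
    diversity_group: pd.DataFrame
    kinship_flags: pd.DataFrame
    selfing_table: pd.DataFrame
    q_matrix: pd.DataFrame | None
    evanno: pd.DataFrame | None
    recency: pd.DataFrame
    sfs_paths: dict[str, Path]
    divergence: pd.DataFrame
    notices: list[str]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    """Load and validate a pipeline config from a YAML path or a dict."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    cfg = _merge(DEFAULT_CONFIG, raw or {})
    if raw and "input" in raw:
        cfg["input"] = dict(raw["input"])  # an explicit input replaces, not merges
    inp = cfg["input"]
    if "preset" not in inp and "path" not in inp:
        raise ValueError("input: must give either 'preset' or 'path'+'format'")
    if "path" in inp and "format" not in inp:
        raise ValueError("input.format is required with input.path")
    ks = cfg["ancestry"]["k_values"]
    if any(k < 1 for k in ks):
        raise ValueError("ancestry.k_values must be >= 1")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _kinship_flags(gm: GenotypeMatrix, within_population: bool) -> pd.DataFrame:
    km = king_kinship(gm, within_population=within_population)
    flags = km.pairs_above(FIRST_DEGREE_LO)
    if len(flags) == 0:
        return pd.DataFrame(columns=["sample_i", "sample_j", "phi", "n_loci", "flag"])
    flags = flags.copy()
    flags["flag"] = np.where(flags["phi"] > CLONE_PHI, "duplicate/clone",
                             np.where(flags["phi"] >= FIRST_DEGREE_HI,
                                      "first-degree", "close relative"))
    return flags


def run_pipeline(config_source, gm: GenotypeMatrix | None = None) -> PipelineReport:
    """Run the full analysis; returns a :class:`PipelineReport`.

    ``config_source`` is a YAML path or dict (missing keys fall back to
    :data:`DEFAULT_CONFIG`). If ``gm`` is given it overrides the configured
    input. Stage failures raise; degenerate configurations (e.g. a K sweep
    too short for Evanno) skip the stage with a logged notice recorded in
    ``report.notices``.
    """
    cfg = load_config(config_source)
    rng = np.random.default_rng(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    lineage_of_pop: dict[str, str] = {}

    t0 = time.perf_counter()
    if gm is None:
        inp = cfg["input"]
        if "preset" in inp:
            gm, _truth, scen = simulate_study(inp["preset"], seed=cfg["seed"],
                                              n_loci=inp.get("n_loci", 6000))
            lineage_of_pop = {p.label: p.lineage for p in scen.populations}
        else:
            gm = read_genotypes(inp["path"], inp["format"])
    log.info("input: %d individuals x %d loci (%.2fs)",
             gm.n_individuals, gm.n_loci, time.perf_counter() - t0)

    # -- filter -----------------------------------------------------------
    fcfg = cfg["filter"]
    gm = filter_loci(gm, fcfg["max_missing_frac"], fcfg["min_maf"])
    log.info("filter: %d loci retained", gm.n_loci)

    # -- kinship screen ----------------------------------------------------
    flags = _kinship_flags(gm, cfg["kinship"]["within_population"])
    flags.to_csv(outdir / "kinship_flags.tsv", sep="\t", index=False)

    # -- diversity ---------------------------------------------------------
    div = diversity_summary(gm)
    div.per_individual.to_csv(outdir / "diversity_individual.tsv", sep="\t",
                              index=False, float_format="%.6g")
    div.per_group.to_csv(outdir / "diversity_group.tsv", sep="\t",
                         index=False, float_format="%.6g")

    # -- selfing per population --------------------------------------------
    scfg = cfg["selfing"]
    srows = []
    for pop, idx in gm.population_indices().items():
        if len(idx) < 3:
            notices.append(f"selfing: population {pop} skipped (n < 3)")
            continue
        est = estimate_selfing(gm, idx, max_loci=scfg["max_loci"],
                               n_perm=scfg["n_perm"], n_boot=scfg["n_boot"],
                               seed=rng)
        ho = div.per_group.set_index("group").loc[pop, "h_obs"]
        srows.append((pop, len(idx), ho, est.s_hat, est.sd_s, est.p_value,
                      est.g2_hat, est.n_loci_used))
    selfing_table = pd.DataFrame(
        srows, columns=["group", "n", "h_obs", "s_hat", "sd_s", "p_value",
                        "g2_hat", "n_loci_used"])

    # -- ancestry: K sweep, Evanno, main Q ---------------------------------
    acfg = cfg["ancestry"]
    sub = gm
    if acfg["subsample_loci"] and gm.n_loci > acfg["subsample_loci"]:
        keep = np.sort(rng.choice(gm.n_loci, acfg["subsample_loci"],
                                  replace=False))
        sub = gm.take_loci(keep)
    ks = sorted(acfg["k_values"])
    evanno_df = None
    q_df = None
    best_by_k = {}
    if len(ks) >= 1:
        loglik: dict[int, list[float]] = {}
        for k in ks:
            loglik[k] = []
            for rep in range(acfg["replicates"]):
                res = admixture_em(sub, k, n_restarts=acfg["n_restarts"],
                                   max_iter=acfg["max_iter"],
                                   seed=int(rng.integers(2**31)))
                loglik[k].append(res.log_likelihood)
                if rep == 0 or res.log_likelihood > best_by_k[k].log_likelihood:
                    best_by_k[k] = res
        if len(ks) >= 3 and acfg["replicates"] >= 2 and \
                all(b - a == 1 for a, b in zip(ks, ks[1:])):
            evanno_df = evanno_delta_k(loglik).table
            evanno_df.to_csv(outdir / "evanno.tsv", sep="\t", index=False,
                             float_format="%.6g")
        else:
            notices.append("ancestry: Evanno stage skipped "
                           "(needs >= 3 consecutive K with >= 2 replicates)")
            log.info("Evanno stage skipped for this K range")
        k_main = acfg["k_main"] or max(ks)
        main = best_by_k[k_main]
        q_df = pd.DataFrame(main.Q, columns=[f"q{j + 1}" for j in range(k_main)])
        q_df.insert(0, "sample_id", gm.sample_ids)
        q_df.insert(1, "population", gm.population_labels)
        q_df["admixture_degree"] = admixture_degree(main.Q)
        q_df.to_csv(outdir / "q_matrix.tsv", sep="\t", index=False,
                    float_format="%.6g")
        if acfg.get("pca_components"):
            pca = pca_mean_impute(gm, acfg["pca_components"])
            pd.DataFrame(pca.scores,
                         columns=[f"PC{j + 1}" for j in range(pca.scores.shape[1])]
                         ).assign(sample_id=gm.sample_ids).to_csv(
                outdir / "pca_scores.tsv", sep="\t", index=False,
                float_format="%.6g")

    # -- cluster labeling, per-cluster selfing and SFS ----------------------
    hcfg = cfg["hybrids"]
    recency = pd.DataFrame(columns=["sample_id", "q", "h_obs", "envelope_lo",
                                    "envelope_hi", "n_matched_sims", "call",
                                    "pair"])
    sfs_paths: dict[str, Path] = {}
    if q_df is not None:
        main = best_by_k[cfg["ancestry"]["k_main"] or max(ks)]
        Q = main.Q
        cluster_of_label = _map_clusters(Q, gm, lineage_of_pop)
        thr = acfg["purity_threshold"]
        for label, k in sorted(cluster_of_label.items()):
            idx = np.flatnonzero(Q[:, k] >= thr)
            if len(idx) >= 3:
                est = estimate_selfing(gm, idx, max_loci=scfg["max_loci"],
                                       n_perm=scfg["n_perm"],
                                       n_boot=scfg["n_boot"], seed=rng)
                ho = float(np.nanmean(observed_heterozygosity(
                    gm.take_individuals(idx))))
                selfing_table.loc[len(selfing_table)] = (
                    f"cluster:{label}", len(idx), ho, est.s_hat, est.sd_s,
                    np.nan if est.p_value is None else est.p_value,
                    est.g2_hat, est.n_loci_used)
            # folded SFS per cluster
            if len(idx) >= 2:
                sfs = folded_sfs(gm.take_individuals(idx),
                                 projection_n=cfg["sfs"]["projection_n"])
                path = outdir / f"sfs_{label}.txt"
                write_sfs(sfs, path)
                sfs_paths[str(label)] = path

    # -- hybrids: pair-restricted reanalysis and recency calls --------------
    # Each pair gets its own two-cluster fit on the populations dominated by
    # the two parental lineages (a supervised rerun, as in reference-panel
    # hybrid analyses); this is far more stable than carving parental pools
    # out of the global K-cluster solution.
    all_calls = []
    assigned = {p for p in gm.population_labels if p in lineage_of_pop}
    unassigned = [p for p in dict.fromkeys(gm.population_labels)
                  if p not in assigned] if lineage_of_pop else []
    for pair in hcfg["pairs"]:
        try:
            calls, sims = analyze_pair(
                gm, _pair_pops(pair[0], gm, lineage_of_pop),
                _pair_pops(pair[1], gm, lineage_of_pop),
                extra_pops=unassigned,
                n_per_class=hcfg["n_per_class"], q_window=hcfg["q_window"],
                band=tuple(hcfg["band"]), min_matches=hcfg["min_matches"],
                purity_threshold=cfg["ancestry"]["purity_threshold"],
                subsample_loci=cfg["ancestry"]["subsample_loci"],
                n_restarts=cfg["ancestry"]["n_restarts"],
                max_iter=cfg["ancestry"]["max_iter"],
                seed=int(rng.integers(2**31)))
        except ValueError as exc:
            notices.append(f"hybrids {pair}: {exc}")
            continue
        if len(calls) == 0:
            notices.append(f"hybrids {pair}: no admixed candidates")
            continue
        calls["pair"] = f"{pair[0]}-{pair[1]}"
        all_calls.append(calls)
        sims.table.to_csv(outdir / f"hybrid_sims_{pair[0]}-{pair[1]}.tsv",
                          sep="\t", index=False, float_format="%.6g")
    if all_calls:
        recency = pd.concat(all_calls, ignore_index=True)
    recency.to_csv(outdir / "recency_calls.tsv", sep="\t", index=False,
                   float_format="%.6g")
    selfing_table.to_csv(outdir / "selfing.tsv", sep="\t", index=False,
                         float_format="%.6g")

    # -- divergence-time conversions ----------------------------------------
    dcfg = cfg["divergence"]
    drows = [vars(divergence_time(t, dcfg["mu"], dcfg["generation_time"]))
             for t in dcfg["tau_values"]]
    divergence = pd.DataFrame(drows, columns=["tau", "mu", "generation_time",
                                              "t_years"])
    divergence.to_csv(outdir / "divergence_times.tsv", sep="\t", index=False,
                      float_format="%.10g")

    meta = {"seed": cfg["seed"], "config_hash": _config_hash(cfg),
            "selfkit_version": __version__, "numpy_version": np.__version__,
            "notices": notices}
    with open(outdir / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    return PipelineReport(cfg, meta["config_hash"], outdir,
                          div.per_individual, div.per_group, flags,
                          selfing_table, q_df, evanno_df, recency, sfs_paths,
                          divergence, notices)


def _map_clusters(Q: np.ndarray, gm: GenotypeMatrix,
                  lineage_of_pop: dict[str, str]) -> dict[str, int]:
    """Name each cluster after the population (or lineage) it dominates."""
    pops = gm.population_indices()
    labels: dict[str, int] = {}
    for k in range(Q.shape[1]):
        means = {p: Q[idx, k].mean() for p, idx in pops.items()}
        top = max(means, key=means.get)
        label = lineage_of_pop.get(top, top)
        if label in labels:
            label = f"{label}_{k}"
        labels[label] = k
    return labels


def _pair_pops(item, gm: GenotypeMatrix,
               lineage_of_pop: dict[str, str]) -> list[str]:
    """Resolve one side of a hybrid pair to population labels.

    A list is taken literally as population labels; a string names a lineage
    (requires lineage metadata, i.e. a preset run).
    """
    if isinstance(item, (list, tuple)):
        return list(item)
    pops = [p for p, lin in lineage_of_pop.items() if lin == item]
    if not pops:
        raise ValueError(f"unknown lineage {item!r} "
                         "(pass population labels as a list for user data)")
    return pops
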