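"""Maximum-likelihood admixture-model clustering and ancestry statistics.

The model is the standard admixture likelihood over unlinked biallelic
loci: individual i's two alleles at locus l are independent draws from a
mixture of K cluster allele frequencies ``p_kl`` with individual-specific
membership fractions ``q_ik``, so the genotype log-likelihood is

    sum_il [ g_il log f_il + (2 - g_il) log(1 - f_il) ],
    f_il = sum_k q_ik p_kl.

It is maximized by EM (expected ancestry-of-allele counts in the E-step,
closed-form ratios in the M-step) with multiple seeded restarts; this is a
deliberate maximum-likelihood stand-in for Bayesian MCMC clustering, with
the same likelihood family and equivalent Q/P outputs. Missing genotypes
are skipped, with per-individual normalization by called loci.

Also here: the supervised two-parental ancestry coefficient, the Evanno
delta-K table for choosing K from replicate log-likelihoods, the
admixture-degree statistic (row SD of Q), and mean-imputed PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotypes import MISSING, GenotypeMatrix

_FREQ_EPS = 1e-6


@dataclass
class AncestryResult:
    """EM admixture fit: Q (n x K memberships), P (K x L frequencies)."""

    Q: np.ndarray
    P: np.ndarray
    log_likelihood: float
    K: int
    n_restarts: int
    seed: int | None
    converged: bool
    n_iter: int
    log_likelihood_path: np.ndarray  # best restart's per-iteration trace


@dataclass
class EvannoTable:
    """Per-K replicate log-likelihood summary with the delta-K statistic."""

    table: pd.DataFrame  # columns: K, mean_lnL, sd_lnL, delta_k

    def best_k(self) -> int | None:
        t = self.table.dropna(subset=["delta_k"])
        return int(t.loc[t["delta_k"].idxmax(), "K"]) if len(t) else None


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray


def _masked_genotypes(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    called = gm.called
    g = np.where(called, gm.genotypes, 0).astype(np.float64)
    return g, called.astype(np.float64)


def admixture_em(gm: GenotypeMatrix, K: int, n_restarts: int = 10,
                 tol: float = 1e-6, max_iter: int = 2000,
                 seed: int | None = None) -> AncestryResult:
    """Fit the K-cluster admixture model by EM, best of ``n_restarts``.

    Initialization per restart: Q rows ~ symmetric Dirichlet(1), P entries ~
    Uniform(0.05, 0.95). Convergence when the log-likelihood improves by
    less than ``tol``; the log-likelihood is non-decreasing along every EM
    path (a property asserted in the test suite). Restart ties are broken by
    restart index. Raises if K exceeds the number of individuals.
    """
    n, L = gm.n_individuals, gm.n_loci
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K = {K} exceeds the {n} individuals")
    g, m = _masked_genotypes(gm)  # g: alt counts (0 where missing), m: called mask
    gq = g                      # alt-allele count per called locus
    gr = 2.0 * m - g            # ref-allele count per called locus
    rng = np.random.default_rng(seed)
    best: AncestryResult | None = None
    for restart in range(n_restarts):
        Q = rng.dirichlet(np.ones(K), size=n)
        P = rng.uniform(0.05, 0.95, size=(K, L))
        path = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            F = Q @ P
            F = np.clip(F, _FREQ_EPS, 1.0 - _FREQ_EPS)
            ll = float(np.sum(gq * np.log(F) + gr * np.log(1.0 - F)))
            path.append(ll)
            if ll - prev < tol and it > 1:
                converged = True
                break
            prev = ll
            # E-step responsibilities folded into the M-step sufficient stats:
            # expected alt-allele ancestry counts A_ik_l = gq * q_ik p_kl / F,
            # ref counts B = gr * q_ik (1 - p_kl) / (1 - F).
            inv_f = gq / F
            inv_r = gr / (1.0 - F)
            # Both updates use the responsibilities of the current (Q, P).
            A = Q * (inv_f @ P.T)          # (n, K): sum_l expected alt counts
            B = Q * (inv_r @ (1.0 - P).T)  # (n, K): sum_l expected ref counts
            alt_kl = P * (Q.T @ inv_f)       # (K, L) expected alt counts
            ref_kl = (1.0 - P) * (Q.T @ inv_r)
            alleles = 2.0 * m.sum(axis=1, keepdims=True)
            Q = (A + B) / np.maximum(alleles, 1.0)
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                P = alt_kl / np.maximum(alt_kl + ref_kl, 1e-300)
            P = np.clip(P, _FREQ_EPS, 1.0 - _FREQ_EPS)
        cand = AncestryResult(Q, P, path[-1], K, n_restarts, seed, converged,
                              it, np.asarray(path))
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def admixture_log_likelihood(gm: GenotypeMatrix, Q: np.ndarray,
                             P: np.ndarray) -> float:
    """Log-likelihood of a (Q, P) pair under the admixture model."""
    g, m = _masked_genotypes(gm)
    F = np.clip(Q @ P, _FREQ_EPS, 1.0 - _FREQ_EPS)
    return float(np.sum(g * np.log(F) + (2.0 * m - g) * np.log(1.0 - F)))


def supervised_ancestry(gm: GenotypeMatrix, freqs_a: np.ndarray,
                        freqs_b: np.ndarray) -> np.ndarray:
    """Per-individual ancestry coefficient q given two parental allele pools.

    Maximizes the binomial likelihood with per-locus allele frequency
    ``f_l = q p_Al + (1 - q) p_Bl`` by bounded 1-D optimization; parental
    frequencies are clipped away from 0/1. Individuals with no called loci
    get NaN.
    """
    pa = np.clip(np.asarray(freqs_a, dtype=float), _FREQ_EPS, 1.0 - _FREQ_EPS)
    pb = np.clip(np.asarray(freqs_b, dtype=float), _FREQ_EPS, 1.0 - _FREQ_EPS)
    if pa.shape != pb.shape or pa.size != gm.n_loci:
        raise ValueError("parental frequency vectors must match the loci")
    out = np.empty(gm.n_individuals)
    for i in range(gm.n_individuals):
        row = gm.genotypes[i]
        called = row != MISSING
        if not called.any():
            out[i] = np.nan
            continue
        g = row[called].astype(float)
        a, b = pa[called], pb[called]

        def nll(q):
            f = np.clip(q * a + (1.0 - q) * b, _FREQ_EPS, 1.0 - _FREQ_EPS)
            return -np.sum(g * np.log(f) + (2.0 - g) * np.log(1.0 - f))

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-8})
        out[i] = float(res.x)
    return out


def evanno_delta_k(loglik_by_k: dict[int, list[float]]) -> EvannoTable:
    """Evanno delta-K from replicate log-likelihoods per K.

    ``delta_k(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / SD_r(L_r(K))``,
    defined only at interior K values with positive replicate SD and with
    matching replicate counts available at K-1, K, K+1. Requires at least
    three consecutive K values with >= 2 replicates each.
    """
    ks = sorted(loglik_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    reps = {k: np.asarray(loglik_by_k[k], dtype=float) for k in ks}
    if any(len(v) < 2 for v in reps.values()):
        raise ValueError("need >= 2 replicates per K")
    rows = []
    for k in ks:
        mean = reps[k].mean()
        sd = reps[k].std(ddof=1)
        dk = np.nan
        if k - 1 in reps and k + 1 in reps:
            nr = min(len(reps[k - 1]), len(reps[k]), len(reps[k + 1]))
            second = np.abs(reps[k + 1][:nr] - 2.0 * reps[k][:nr] + reps[k - 1][:nr])
            dk = second.mean() / sd if sd > 0 else np.nan
        rows.append((k, mean, sd, dk))
    return EvannoTable(pd.DataFrame(rows, columns=["K", "mean_lnL", "sd_lnL",
                                                   "delta_k"]))


def admixture_degree(Q: np.ndarray) -> np.ndarray:
    """Degree of admixed ancestry: population SD (divisor K) of each Q row.

    0 for a uniform row (maximally admixed), maximal
    (``sqrt(K - 1) / K``) for a pure row.
    """
    Q = np.asarray(Q, dtype=float)
    return Q.std(axis=1, ddof=0)


def align_clusters(Q_ref: np.ndarray, Q_other: np.ndarray) -> np.ndarray:
    """Column permutation aligning ``Q_other`` to ``Q_ref`` (greedy by correlation)."""
    K = Q_ref.shape[1]
    corr = np.corrcoef(Q_ref.T, Q_other.T)[:K, K:]
    corr = np.nan_to_num(corr, nan=-np.inf)
    perm = np.full(K, -1)
    used = set()
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        perm[i] = j
        used.add(j)
        corr[i, :] = -np.inf
        corr[:, j] = -np.inf
    return perm


def pca_mean_impute(gm: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the genotype matrix with per-locus mean imputation of missing calls.

    Columns are centered (no scaling); scores come from the SVD of the
    centered matrix and are deterministic up to sign.
    """
    if gm.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    if n_components > min(gm.n_individuals, gm.n_loci):
        raise ValueError("n_components exceeds matrix rank bound")
    from sklearn.decomposition import PCA

    called = gm.called
    X = gm.genotypes.astype(float)
    col_mean = np.where(called.any(axis=0),
                        np.where(called, X, 0).sum(axis=0)
                        / np.maximum(called.sum(axis=0), 1), 0.0)
    X = np.where(called, X, col_mean[None, :])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(scores, pca.explained_variance_ratio_)
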