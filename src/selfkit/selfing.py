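"""Multilocus selfing-rate estimation from identity disequilibrium.

Under mixed mating at equilibrium an individual's count of consecutive
selfing ancestor generations G is geometric with parameter s. Averaging the
per-individual inbreeding level 1 - 2^-G gives the classical
F_IS = s / (2 - s); the *variance* of inbreeding across individuals makes
heterozygosity covary across loci within individuals, quantified by the
identity-disequilibrium statistic

    g2 = E[h_l h_m] / (E[h_l] E[h_m]) - 1     (l != m),

which under the geometric-G model equals s / ((1 - s)(4 - s)). Estimating
g2 from heterozygosity indicators and inverting that map yields a
multilocus selfing-rate estimate that is robust to the base level of
heterozygosity (the RMES idea). A one-sided permutation test that shuffles
each locus's heterozygosity column independently across individuals
provides the null (no identity disequilibrium), and a locus bootstrap gives
the standard error of s-hat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class G2Result:
    """Multilocus identity disequilibrium with its intermediate sums."""

    g2: float
    numerator: float
    denominator: float
    n_individuals: int
    n_loci: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.g2)


@dataclass
class SelfingEstimate:
    """g2-based selfing-rate estimate (one population or lineage group)."""

    g2_hat: float
    s_hat: float
    sd_s: float
    p_value: float | None
    n_perm: int
    n_boot: int
    n_loci_used: int
    n_individuals: int
    negative_g2: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.g2_hat)


def _het_matrix(gm_or_h, max_locus_missing: float = 0.2
                ) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygosity indicators (missing -> 0) and the called mask.

    Loci whose within-group missingness exceeds ``max_locus_missing`` are
    dropped before anything else; the remaining missing entries contribute 0
    to every sum (complete-case masking inside the closed form).
    """
    if isinstance(gm_or_h, GenotypeMatrix):
        geno = gm_or_h.genotypes
        called = geno != MISSING
        keep = called.mean(axis=0) >= 1.0 - max_locus_missing
        geno = geno[:, keep]
        called = called[:, keep]
        h = ((geno == 1) & called).astype(np.float64)
        return h, called
    h = np.asarray(gm_or_h, dtype=np.float64)
    return h, np.ones_like(h, dtype=bool)


def _g2_from_sums(r: np.ndarray, c_sq_sum: float, T: float, n: int
                  ) -> tuple[float, float, float]:
    num = float(np.sum(r * r - r)) / n
    den = (T * T - float(np.sum(r * r)) - c_sq_sum + T) / (n * (n - 1))
    g2 = num / den - 1.0 if den > 0 else np.nan
    return g2, num, den


def multilocus_g2(gm_or_h, max_locus_missing: float = 0.2) -> G2Result:
    """Closed-form multilocus identity disequilibrium.

    With heterozygosity indicators ``h_il``, row sums ``r_i``, column sums
    ``c_l`` and total ``T``::

        g2_hat = [ (1/n) sum_i (r_i^2 - r_i) ]
                 / [ (1/(n(n-1))) (T^2 - sum_i r_i^2 - sum_l c_l^2 + T) ] - 1

    i.e. the mean within-individual cross-locus co-heterozygosity over its
    between-individual (independence) expectation, minus one. Accepts a
    :class:`~selfkit.genotypes.GenotypeMatrix` or a 0/1 indicator array.
    A zero denominator (no between-individual heterozygosity cross-products)
    yields an undefined (NaN) g2, never an exception.
    """
    h, _ = _het_matrix(gm_or_h, max_locus_missing)
    n, L = h.shape
    if n < 3:
        raise ValueError("multilocus_g2 needs at least 3 individuals")
    if L < 2:
        raise ValueError("multilocus_g2 needs at least 2 usable loci")
    r = h.sum(axis=1)
    c = h.sum(axis=0)
    T = float(r.sum())
    g2, num, den = _g2_from_sums(r, float(np.sum(c * c)), T, n)
    return G2Result(g2, num, den, n, L)


def g2_to_selfing(g2: float) -> tuple[float, bool]:
    """Invert g2 = s / ((1 - s)(4 - s)) for s in [0, 1).

    Solves the quadratic ``g2 s^2 - (5 g2 + 1) s + 4 g2 = 0`` for its root in
    [0, 1). Negative g2 maps to s = 0 with a flag (second return value);
    undefined g2 propagates NaN.
    """
    if not np.isfinite(g2):
        return np.nan, False
    if g2 <= 0.0:
        return 0.0, g2 < 0.0
    b = 5.0 * g2 + 1.0
    s = (b - np.sqrt(b * b - 16.0 * g2 * g2)) / (2.0 * g2)
    return float(min(max(s, 0.0), 1.0)), False


def selfing_to_g2(s: float) -> float:
    """Forward map s -> g2 under the geometric selfing-depth model."""
    if not 0.0 <= s < 1.0:
        raise ValueError("s must be in [0, 1)")
    return s / ((1.0 - s) * (4.0 - s))


def fis_to_selfing(F: float) -> tuple[float, bool]:
    """Selfing rate from the inbreeding coefficient: s = 2F / (1 + F).

    Negative F maps to s = 0 with a flag; F = -1 is undefined (NaN).
    """
    if not -1.0 <= F <= 1.0:
        raise ValueError("F must be in [-1, 1]")
    if F == -1.0:
        return np.nan, True
    if F < 0.0:
        return 0.0, True
    return float(min(2.0 * F / (1.0 + F), 1.0)), False


def estimate_selfing(gm: GenotypeMatrix, individuals=None, max_loci: int = 1000,
                     n_perm: int = 10000, n_boot: int = 1000, seed=None,
                     max_locus_missing: float = 0.2) -> SelfingEstimate:
    """Full multilocus selfing-rate estimate for one group of individuals.

    Subsamples ``max_loci`` loci without replacement when more are
    available, computes g2-hat and s-hat, a one-sided permutation p-value
    (each locus's heterozygosity column permuted independently across
    individuals, destroying cross-locus association while preserving
    per-locus heterozygote counts; finite-sample convention
    ``p = (1 + exceedances) / (1 + n_perm)``), and a bootstrap SD of s-hat
    obtained by resampling individuals (see inline note). Set ``n_perm=0`` /
    ``n_boot=0`` to skip either resampling stage.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sub = gm if individuals is None else gm.take_individuals(np.asarray(individuals))
    if sub.n_individuals < 3:
        raise ValueError("estimate_selfing needs at least 3 individuals")
    if sub.n_loci > max_loci:
        keep = np.sort(rng.choice(sub.n_loci, size=max_loci, replace=False))
        sub = sub.take_loci(keep)
    h, _ = _het_matrix(sub, max_locus_missing)
    n, L = h.shape
    if L < 2 or h.sum() == 0:
        return SelfingEstimate(np.nan, np.nan, np.nan, None, 0, 0, L, n)
    base = multilocus_g2(h)
    s_hat, neg = g2_to_selfing(base.g2)

    p_value = None
    if n_perm > 0 and base.defined:
        exceed = 0
        for _ in range(n_perm):
            hp = rng.permuted(h, axis=0)
            r = hp.sum(axis=1)
            g2p, _, _ = _g2_from_sums(r, float(np.sum(hp.sum(axis=0) ** 2)),
                                      float(r.sum()), n)
            if np.isfinite(g2p) and g2p >= base.g2:
                exceed += 1
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    sd_s = np.nan
    if n_boot > 0 and base.defined:
        # Bootstrap over individuals: the dominant sampling variance of g2
        # is the between-individual variance in realized inbreeding (the
        # finite draw of selfing depths G), which resampling loci leaves
        # fixed. Weights w_i ~ Multinomial(n, 1/n) enter the closed-form
        # sums directly.
        r = h.sum(axis=1)
        W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)  # (n_boot, n)
        C = W @ h                                   # column sums per draw
        c_sq = (C * C).sum(axis=1)
        T_b = W @ r
        num = (W @ (r * r - r)) / n
        den = (T_b * T_b - W @ (r * r) - c_sq + T_b) / (n * (n - 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            g2_b = np.where(den > 0, num / den - 1.0, np.nan)
        # SD on a signed extension of the g2 -> s map (s(|g2|) with the sign
        # of g2): avoids spread compression from the pile-up at s = 0.
        s_b = np.array([np.sign(g) * g2_to_selfing(abs(g))[0]
                        for g in g2_b if np.isfinite(g)])
        sd_s = float(np.std(s_b, ddof=1)) if s_b.size > 1 else np.nan

    return SelfingEstimate(base.g2, s_hat, sd_s, p_value, n_perm, n_boot, L, n,
                           negative_g2=neg)
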