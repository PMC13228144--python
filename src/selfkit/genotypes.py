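"""Genotype data model, file I/O, filtering, diversity, kinship, and folded SFS.

The universal currency of the package is the :class:`GenotypeMatrix`:
individuals x unlinked biallelic loci coded as the count of the alternate
(second) allele, 0/1/2, with a single missing sentinel (:data:`MISSING`).
All statistics are complete-case per locus or per pair of individuals; no
imputation happens here (mean imputation exists only inside the PCA helper
of :mod:`selfkit.ancestry`).

Supported on-disk formats are deliberately plain text: VCF (biallelic SNPs,
GT field only), the two-row-per-individual STRUCTURE integer format
(missing = -9), and a TSV 0/1/2 matrix.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of biallelic genotype codes.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2}`` (count of the alternate allele) or :data:`MISSING`.
    sample_ids
        Unique identifier per individual (row).
    population_labels
        Non-empty population label per individual.
    locus_ids
        Unique identifier per locus (column).
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.population_labels = [str(p) for p in self.population_labels]
        self.locus_ids = [str(l) for l in self.locus_ids]
        n, L = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.population_labels) != n:
            raise ValueError("population_labels length mismatch")
        if len(self.locus_ids) != L:
            raise ValueError(f"{len(self.locus_ids)} locus_ids for {L} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids must be unique")
        if any(p == "" for p in self.population_labels):
            raise ValueError("population_labels must be non-empty")
        bad = ~np.isin(self.genotypes, list(_VALID_CODES))
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[:3]}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.genotypes != MISSING

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.genotypes[idx],
            [self.sample_ids[i] for i in idx],
            [self.population_labels[i] for i in idx],
            list(self.locus_ids),
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.sample_ids),
            list(self.population_labels),
            [self.locus_ids[i] for i in idx],
        )

    def population_indices(self) -> dict[str, np.ndarray]:
        """Indices of individuals per population, in first-seen order."""
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.population_labels):
            out.setdefault(p, []).append(i)
        return {p: np.asarray(ix) for p, ix in out.items()}

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over called genotypes (NaN if none)."""
        called = self.called
        g = np.where(called, self.genotypes, 0).astype(float)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, g.sum(axis=0) / (2.0 * n_called), np.nan)


@dataclass
class DiversitySummary:
    """Observed/expected heterozygosity and inbreeding summaries.

    ``per_individual`` has columns ``sample_id, group, h_obs, missing_frac,
    n_called`` (``h_obs`` is NaN-flagged for individuals with no called loci).
    ``per_group`` has columns ``group, n, h_obs, h_exp, f_is`` where ``h_exp``
    is Nei's unbiased gene diversity averaged over loci and
    ``f_is = 1 - mean(H_O)/mean(H_E)``.
    """

    per_individual: pd.DataFrame
    per_group: pd.DataFrame


@dataclass
class KinshipMatrix:
    """Symmetric KING-robust kinship coefficients.

    ``phi[i, j]`` is NaN when undefined (no jointly-called heterozygous loci,
    or the pair crosses populations under within-population mode).
    """

    phi: np.ndarray
    n_loci_used: np.ndarray
    sample_ids: list[str]

    def pairs_above(self, threshold: float) -> pd.DataFrame:
        """Upper-triangle pairs with defined phi >= threshold."""
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                v = self.phi[i, j]
                if np.isfinite(v) and v >= threshold:
                    rows.append((self.sample_ids[i], self.sample_ids[j], v,
                                 int(self.n_loci_used[i, j])))
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi", "n_loci"])


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum: counts of minor-allele classes 0..n/2."""

    counts: np.ndarray
    n_alleles: int
    n_loci_used: int

    def to_line(self) -> str:
        """Single-line whitespace-separated representation."""
        return " ".join(f"{c:g}" for c in self.counts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("vcf", "structure", "matrix012")

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_TO_CODE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
               "1/1": 2, "1|1": 2}


def read_genotypes(path: str | os.PathLike, format: str,
                   default_population: str = "unknown") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``format`` is one of ``vcf``, ``structure``, ``matrix012``. VCF and the
    0/1/2 matrix carry no population metadata; individuals are assigned
    ``default_population``. Multi-allelic or indel VCF records are rejected
    with the offending locus named.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, default_population)
    if format == "structure":
        return _read_structure(path)
    return _read_matrix012(path, default_population)


def write_genotypes(gm: GenotypeMatrix, path: str | os.PathLike, format: str) -> None:
    """Write ``gm`` to ``path`` in the given format (bit-stable per input)."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = os.fspath(path)
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "structure":
        _write_structure(gm, path)
    else:
        _write_matrix012(gm, path)


def _read_vcf(path: str, default_population: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    for v in vcf:
        lid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise ValueError(f"locus {lid}: not biallelic (ALT={','.join(v.ALT)})")
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValueError(f"locus {lid}: indel records are not supported")
        gt = np.asarray(v.genotype.array())  # (n, 3): allele_a, allele_b, phased
        a, b = gt[:, 0].astype(int), gt[:, 1].astype(int)
        code = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        cols.append(code)
        locus_ids.append(lid)
    vcf.close()
    n = len(samples)
    geno = (np.column_stack(cols) if cols
            else np.empty((n, 0), dtype=np.int8))
    return GenotypeMatrix(geno, samples, [default_population] * n, locus_ids)


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    # Placeholder CHROM/POS: the loci are unlinked tags, positions carry no
    # meaning; locus identity lives in the ID column.
    buf = io.StringIO()
    buf.write(_VCF_HEADER)
    buf.write("##contig=<ID=1>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(gm.sample_ids) + "\n")
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for l, lid in enumerate(gm.locus_ids):
        gts = "\t".join(code_to_gt[int(g)] for g in gm.genotypes[:, l])
        buf.write(f"1\t{l + 1}\t{lid}\tA\tT\t.\t.\t.\tGT\t{gts}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _write_structure(gm: GenotypeMatrix, path: str) -> None:
    # Two rows per individual; alleles coded 1 (ref) / 2 (alt); missing -9.
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "population"] + gm.locus_ids) + "\n")
        for i, (sid, pop) in enumerate(zip(gm.sample_ids, gm.population_labels)):
            row = gm.genotypes[i]
            first = ["-9" if g == MISSING else ("2" if g == 2 else "1") for g in row]
            second = ["-9" if g == MISSING else ("2" if g >= 1 else "1") for g in row]
            fh.write("\t".join([sid, pop] + first) + "\n")
            fh.write("\t".join([sid, pop] + second) + "\n")


def _read_structure(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    locus_ids = header[2:]
    body = [ln.split("\t") for ln in lines[1:]]
    if len(body) % 2 != 0:
        raise ValueError("STRUCTURE file must have two rows per individual")
    widths = {len(r) for r in body}
    if widths != {len(header)}:
        raise ValueError("ragged STRUCTURE rows")
    sample_ids, pops, geno_rows = [], [], []
    allele_rows = np.array([[int(x) for x in r[2:]] for r in body], dtype=int)
    L = len(locus_ids)
    for k in range(0, len(body), 2):
        if body[k][0] != body[k + 1][0]:
            raise ValueError(f"unpaired individual rows near {body[k][0]!r}")
        sample_ids.append(body[k][0])
        pops.append(body[k][1])
    a1 = allele_rows[0::2]
    a2 = allele_rows[1::2]
    # Dialect: allele codes 1 (reference) / 2 (alternate) as written by
    # write_genotypes. Other integer codes are accepted per column with the
    # smaller code taken as reference; a column monomorphic for an unknown
    # code is called reference-homozygous (the coding is then ambiguous).
    geno = np.zeros(a1.shape, dtype=np.int8)
    for l in range(L):
        col = np.concatenate([a1[:, l], a2[:, l]])
        present = np.unique(col[col != -9])
        if len(present) > 2:
            raise ValueError(f"locus {locus_ids[l]}: more than two alleles")
        if set(present).issubset({1, 2}):
            second = 2
        elif len(present) == 2:
            second = present.max()
        else:
            second = None
        miss = (a1[:, l] == -9) | (a2[:, l] == -9)
        if second is None:
            cnt = np.zeros(a1.shape[0], dtype=int)
        else:
            cnt = ((a1[:, l] == second).astype(int)
                   + (a2[:, l] == second).astype(int))
        geno[:, l] = np.where(miss, MISSING, cnt)
    return GenotypeMatrix(geno, sample_ids, pops, locus_ids)


def _write_matrix012(gm: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "population"] + gm.locus_ids) + "\n")
        for i, (sid, pop) in enumerate(zip(gm.sample_ids, gm.population_labels)):
            cells = ["NA" if g == MISSING else str(int(g)) for g in gm.genotypes[i]]
            fh.write("\t".join([sid, pop] + cells) + "\n")


def _read_matrix012(path: str, default_population: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError("matrix012 file must start with a sample_id column")
    has_pop = len(df.columns) > 1 and df.columns[1] == "population"
    first_locus = 2 if has_pop else 1
    locus_ids = list(df.columns[first_locus:])
    sample_ids = df["sample_id"].tolist()
    pops = (df["population"].tolist() if has_pop
            else [default_population] * len(sample_ids))
    raw = df.iloc[:, first_locus:].to_numpy(dtype=object)
    geno = np.empty(raw.shape, dtype=np.int8)
    for (i, j), v in np.ndenumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("NA", "", "."):
            geno[i, j] = MISSING
        else:
            geno[i, j] = int(v)
    return GenotypeMatrix(geno, sample_ids, pops, locus_ids)


# ---------------------------------------------------------------------------
# Filtering and diversity
# ---------------------------------------------------------------------------

def filter_loci(gm: GenotypeMatrix, max_missing_frac: float = 1.0,
                min_maf: float = 0.0) -> GenotypeMatrix:
    """Retain loci with missingness <= ``max_missing_frac`` and MAF >= ``min_maf``.

    Minor-allele frequency is computed on called alleles only. Order of the
    surviving loci is preserved; the result may have zero loci.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    called = gm.called
    miss_frac = 1.0 - called.mean(axis=0) if gm.n_individuals else np.zeros(gm.n_loci)
    p = gm.allele_frequencies()
    maf = np.fmin(p, 1.0 - p)  # fmin propagates data where one side is NaN
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep = (miss_frac <= max_missing_frac + 1e-12) & (maf >= min_maf - 1e-12)
    return gm.take_loci(keep)


def observed_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Per-individual H_O: fraction of heterozygous calls among called loci.

    Individuals with no called loci get NaN.
    """
    called = gm.called
    het = gm.genotypes == 1
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, het.sum(axis=1) / n_called, np.nan)


def diversity_summary(gm: GenotypeMatrix,
                      grouping: list[str] | None = None) -> DiversitySummary:
    """Per-individual H_O and per-group H_O, Nei's unbiased H_E and F_IS.

    ``grouping`` defaults to the matrix's population labels; pass lineage
    assignments to summarize per lineage instead. Group H_E at locus l is
    ``(2 n_l / (2 n_l - 1)) * (1 - p^2 - q^2)`` with ``n_l`` the number of
    called individuals; loci called in fewer than 2 individuals are skipped.
    ``F_IS = 1 - mean(H_O) / mean(H_E)``.
    """
    groups = list(grouping) if grouping is not None else list(gm.population_labels)
    if len(groups) != gm.n_individuals:
        raise ValueError("grouping length mismatch")
    h_obs = observed_heterozygosity(gm)
    called = gm.called
    per_ind = pd.DataFrame({
        "sample_id": gm.sample_ids,
        "group": groups,
        "h_obs": h_obs,
        "missing_frac": 1.0 - called.mean(axis=1) if gm.n_loci else 0.0,
        "n_called": called.sum(axis=1),
    })
    rows = []
    order = list(dict.fromkeys(groups))
    garr = np.asarray(groups)
    for grp in order:
        idx = np.flatnonzero(garr == grp)
        sub = gm.take_individuals(idx)
        ho = np.nanmean(h_obs[idx]) if np.isfinite(h_obs[idx]).any() else np.nan
        he = _nei_unbiased_he(sub)
        fis = 1.0 - ho / he if (np.isfinite(he) and he > 0) else np.nan
        rows.append((grp, len(idx), ho, he, fis))
    per_group = pd.DataFrame(rows, columns=["group", "n", "h_obs", "h_exp", "f_is"])
    return DiversitySummary(per_ind, per_group)


def _nei_unbiased_he(gm: GenotypeMatrix) -> float:
    called = gm.called
    n_l = called.sum(axis=0)
    ok = n_l >= 2
    if not ok.any():
        return np.nan
    p = gm.allele_frequencies()[ok]
    n_l = n_l[ok].astype(float)
    he = (2.0 * n_l / (2.0 * n_l - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    return float(np.mean(he))


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

def king_kinship(gm: GenotypeMatrix, within_population: bool = True) -> KinshipMatrix:
    """Allele-frequency-free pairwise kinship (KING-robust).

    For pair (i, j) over loci called in both::

        phi = (N_hetHet - 2 N_oppHom) / (N_het_i + N_het_j)

    where ``N_het_i`` counts i's heterozygous loci among the jointly-called
    ones. Duplicated genotypes (clones) give phi = 0.5 exactly. Pairs with a
    zero denominator are NaN (undefined), never silently 0. By default the
    matrix is computed separately within each population (cross-population
    entries NaN), which avoids biases from allele-frequency differences among
    differentiated populations.
    """
    n = gm.n_individuals
    if n < 2:
        raise ValueError("king_kinship needs at least 2 individuals")
    phi = np.full((n, n), np.nan)
    used = np.zeros((n, n), dtype=int)
    if within_population:
        blocks = gm.population_indices().values()
    else:
        blocks = [np.arange(n)]
    for idx in blocks:
        if len(idx) < 2:
            continue
        sub = gm.genotypes[idx]
        p_phi, p_used = _king_block(sub)
        phi[np.ix_(idx, idx)] = p_phi
        used[np.ix_(idx, idx)] = p_used
    np.fill_diagonal(phi, np.nan)
    np.fill_diagonal(used, 0)
    return KinshipMatrix(phi, used, list(gm.sample_ids))


def _king_block(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = (sub != MISSING)
    het = (sub == 1).astype(np.float64)
    hom0 = (sub == 0).astype(np.float64)
    hom2 = (sub == 2).astype(np.float64)
    calledf = called.astype(np.float64)
    het_het = het @ het.T
    opp_hom = hom0 @ hom2.T + hom2 @ hom0.T
    # i's het count restricted to loci also called in j (and vice versa)
    het_i = het @ calledf.T
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (het_het - 2.0 * opp_hom) / denom, np.nan)
    used = (calledf @ calledf.T).astype(int)
    return phi, used


# ---------------------------------------------------------------------------
# Folded SFS
# ---------------------------------------------------------------------------

def folded_sfs(gm: GenotypeMatrix, individuals=None,
               projection_n: int | None = None) -> FoldedSFS:
    """Folded site-frequency spectrum over a subset of individuals.

    Without projection, only complete-data loci (all subset individuals
    called) are used and minor-allele counts are tallied over
    ``n_alleles = 2 * n_subset``. With ``projection_n`` (an even integer),
    each locus with at least ``projection_n`` called alleles contributes its
    expected hypergeometric down-projection, yielding real-valued counts.
    Total mass equals the number of loci used in both modes.
    """
    if individuals is None:
        sub = gm
    else:
        sub = gm.take_individuals(np.asarray(individuals))
    if sub.n_individuals == 0:
        raise ValueError("individual subset is empty")
    geno = sub.genotypes
    called = sub.called
    alt = np.where(called, geno, 0).sum(axis=0)
    n_called_alleles = 2 * called.sum(axis=0)

    if projection_n is None:
        n_alleles = 2 * sub.n_individuals
        full = n_called_alleles == n_alleles
        d = alt[full]
        minor = np.minimum(d, n_alleles - d)
        counts = np.bincount(minor, minlength=n_alleles // 2 + 1).astype(float)
        return FoldedSFS(counts, n_alleles, int(full.sum()))

    if projection_n % 2 != 0 or projection_n <= 0:
        raise ValueError("projection_n must be a positive even integer")
    if projection_n > 2 * sub.n_individuals:
        raise ValueError("projection_n exceeds the available alleles")
    keep = n_called_alleles >= projection_n
    counts = np.zeros(projection_n // 2 + 1)
    ks = np.arange(projection_n + 1)
    for d, nc in zip(alt[keep], n_called_alleles[keep]):
        pmf = hypergeom.pmf(ks, nc, d, projection_n)
        folded = np.zeros(projection_n // 2 + 1)
        for k in ks:
            folded[min(k, projection_n - k)] += pmf[k]
        counts += folded
    return FoldedSFS(counts, projection_n, int(keep.sum()))


def write_sfs(sfs: FoldedSFS, path: str | os.PathLike) -> None:
    """Write the SFS as a single line of whitespace-separated counts."""
    with open(path, "w") as fh:
        fh.write(sfs.to_line() + "\n")
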