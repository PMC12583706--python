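"""Population data model: genotypes, pedigree, marker codings and the MPH transform.

Conventions used throughout the package:

* Genotype codes count reference alleles (0, 1 or 2).  Parents are inbred
  lines, so in strict mode their codes are restricted to {0, 2}; a hybrid's
  code is exactly the average of its two parents' codes.
* The combined row order of every (n+r) x p matrix is hybrids first, then
  parents, in the order stored on :class:`PopulationGenotypes`.
* Coordinates are 1-based base pairs; intervals are closed; markers are
  sorted by (chromosome, position) at load time.
* Allele frequencies ``p_k`` are estimated from the parent rows only:
  parents define the allele pool and hybrids are deterministic functions of
  the parents, so including hybrids would double-count parents through
  their crosses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel", "Pedigree", "PopulationGenotypes", "CodingMatrices",
    "MPHTransform", "infer_hybrid_genotypes", "build_codings",
    "build_mph_transform", "compute_mph", "pairwise_ld_r2",
    "read_population", "write_population",
]


class PopulationError(ValueError):
    """Raised for invalid genotype / pedigree / phenotype inputs."""


@dataclass
class MarkerPanel:
    """Marker metadata: identifiers, map positions and reference-allele frequencies.

    Positions are 1-based and must be strictly increasing within a
    chromosome.  ``ref_freq`` holds the frequency of the reference allele
    p_k among the parents; every marker must be polymorphic (0 < p_k < 1).
    """

    marker_id: list[str]
    chromosome: list[str]
    position_bp: np.ndarray
    ref_freq: np.ndarray

    def __post_init__(self) -> None:
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.ref_freq = np.asarray(self.ref_freq, dtype=float)
        if not (len(self.marker_id) == len(self.chromosome)
                == len(self.position_bp) == len(self.ref_freq)):
            raise PopulationError("marker panel fields have inconsistent lengths")
        if np.any(self.position_bp < 1):
            raise PopulationError("positions must be 1-based positive integers")
        for chrom in dict.fromkeys(self.chromosome):
            pos = self.position_bp[np.asarray(self.chromosome) == chrom]
            if np.any(np.diff(pos) <= 0):
                raise PopulationError(
                    f"positions not strictly increasing on chromosome {chrom!r}")
        if np.any((self.ref_freq <= 0.0) | (self.ref_freq >= 1.0)):
            bad = [self.marker_id[k] for k in
                   np.where((self.ref_freq <= 0) | (self.ref_freq >= 1))[0][:5]]
            raise PopulationError(
                f"monomorphic markers in panel (p_k in {{0,1}}): {bad}; "
                "apply a MAF filter before building codings")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.ref_freq, 1.0 - self.ref_freq)

    def index_of(self, marker: str) -> int:
        try:
            return self.marker_id.index(marker)
        except ValueError:
            raise PopulationError(f"unknown marker id {marker!r}") from None


@dataclass
class Pedigree:
    """Maps each hybrid to its two (distinct) parental lines."""

    hybrid_id: list[str]
    parent1_id: list[str]
    parent2_id: list[str]

    def __post_init__(self) -> None:
        if not (len(self.hybrid_id) == len(self.parent1_id) == len(self.parent2_id)):
            raise PopulationError("pedigree columns have inconsistent lengths")
        if len(set(self.hybrid_id)) != len(self.hybrid_id):
            dup = [h for h in self.hybrid_id if self.hybrid_id.count(h) > 1]
            raise PopulationError(f"duplicate hybrid ids in pedigree: {sorted(set(dup))}")
        for h, p1, p2 in zip(self.hybrid_id, self.parent1_id, self.parent2_id):
            if p1 == p2:
                raise PopulationError(f"selfed cross for hybrid {h!r}: {p1!r} x {p2!r}")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_id)


@dataclass
class PopulationGenotypes:
    """Parent and derived hybrid genotype codes plus the pedigree.

    ``combined_codes`` stacks hybrids first, then parents -- the row order
    used by every downstream matrix.
    """

    parent_ids: list[str]
    parent_codes: np.ndarray      # r x p, entries in {0,1,2} ({0,2} strict)
    pedigree: Pedigree
    hybrid_codes: np.ndarray      # n x p, derived from parents

    @property
    def n_hybrids(self) -> int:
        return self.hybrid_codes.shape[0]

    @property
    def n_parents(self) -> int:
        return self.parent_codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.parent_codes.shape[1]

    @property
    def combined_ids(self) -> list[str]:
        return list(self.pedigree.hybrid_id) + list(self.parent_ids)

    @property
    def combined_codes(self) -> np.ndarray:
        return np.vstack([self.hybrid_codes, self.parent_codes])

    def parent_allele_freq(self) -> np.ndarray:
        """Reference-allele frequency p_k estimated from the parent rows."""
        return self.parent_codes.mean(axis=0) / 2.0


@dataclass
class CodingMatrices:
    """Raw and centered marker codings on the combined (hybrids, parents) rows.

    M_A = code - 1 (values -1/0/1), M_D = 1 iff heterozygous.  U_A is the
    frequency-centered additive coding (code - 2 p_k); U_D is the classical
    dominance-deviation coding taking -2 p_k^2 / 2 p_k (1-p_k) / -2 (1-p_k)^2
    for codes 0 / 1 / 2.  Columns of M_A and M_D are the vectors m_i and l_i
    entering the heterotic-effect design.
    """

    M_A: np.ndarray
    M_D: np.ndarray
    U_A: np.ndarray
    U_D: np.ndarray
    ref_freq: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.M_A.shape[1]


@dataclass
class MPHTransform:
    """The linear map from stacked (hybrid, parent) phenotypes to MPH values.

    T is sparse n x (n+r): each row has +1 on the hybrid's own column and
    -1/2 on each parent column, so ``T @ y_ori`` is the vector of mid-parent
    heterosis values.  T annihilates the all-ones vector and (because a
    hybrid's additive code is the mean of its parents') the additive coding
    matrix M_A.  The induced residual covariance is R = T T'.
    """

    T: sparse.csr_matrix
    row_order: list[str]
    R: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.R = (self.T @ self.T.T).toarray()

    @property
    def n_hybrids(self) -> int:
        return self.T.shape[0]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Return ``T @ v`` for a vector or matrix aligned with ``row_order``."""
        return self.T @ v


def infer_hybrid_genotypes(parent_ids: list[str], parent_codes: np.ndarray,
                           pedigree: Pedigree, strict: bool = True,
                           ) -> PopulationGenotypes:
    """Derive hybrid genotype codes from parental codes and the pedigree.

    Each hybrid's code is the mean of its parents' codes; with inbred
    parents ({0,2}) the hybrid is heterozygous (code 1) exactly where the
    parents differ.  In strict mode (the default) a heterozygous parent
    call violates the inbred-line assumption and is an error.
    """
    parent_codes = np.asarray(parent_codes, dtype=float)
    if parent_codes.ndim != 2 or parent_codes.shape[0] != len(parent_ids):
        raise PopulationError("parent_codes must be r x p with one row per parent id")
    if not np.isin(parent_codes, (0.0, 1.0, 2.0)).all():
        raise PopulationError("parent codes must be 0, 1 or 2")
    het = np.argwhere(parent_codes == 1.0)
    if strict and het.size:
        i, k = het[0]
        raise PopulationError(
            f"inbred-line violation: parent {parent_ids[i]!r} is heterozygous "
            f"at marker column {k} (strict mode); {len(het)} such calls in total")
    lookup = {pid: idx for idx, pid in enumerate(parent_ids)}
    rows = []
    for h, p1, p2 in zip(pedigree.hybrid_id, pedigree.parent1_id, pedigree.parent2_id):
        for p in (p1, p2):
            if p not in lookup:
                raise PopulationError(f"hybrid {h!r} references unknown parent {p!r}")
        rows.append((parent_codes[lookup[p1]] + parent_codes[lookup[p2]]) / 2.0)
    hybrid_codes = np.asarray(rows, dtype=float)
    return PopulationGenotypes(list(parent_ids), parent_codes, pedigree, hybrid_codes)


def build_codings(pop: PopulationGenotypes, panel: MarkerPanel | None = None,
                  ) -> CodingMatrices:
    """Build the M_A / M_D / U_A / U_D coding matrices on the combined rows.

    Allele frequencies come from ``panel.ref_freq`` when a panel is given,
    otherwise from the parent rows.  Monomorphic columns are an error.
    """
    codes = pop.combined_codes
    p_k = panel.ref_freq if panel is not None else pop.parent_allele_freq()
    p_k = np.asarray(p_k, dtype=float)
    if p_k.shape != (codes.shape[1],):
        raise PopulationError("allele-frequency vector does not match marker count")
    if np.any((p_k <= 0.0) | (p_k >= 1.0)):
        bad = np.where((p_k <= 0) | (p_k >= 1))[0][:5]
        raise PopulationError(
            f"monomorphic marker columns {bad.tolist()}: filter by MAF first")
    M_A = codes - 1.0
    M_D = (codes == 1.0).astype(float)
    U_A = codes - 2.0 * p_k
    # dominance deviation coding: -2p^2 / 2p(1-p) / -2(1-p)^2 for codes 0/1/2
    U_D = np.where(codes == 1.0, 2.0 * p_k * (1.0 - p_k),
                   np.where(codes == 2.0, -2.0 * (1.0 - p_k) ** 2,
                            -2.0 * p_k ** 2))
    return CodingMatrices(M_A=M_A, M_D=M_D, U_A=U_A, U_D=U_D, ref_freq=p_k)


def build_mph_transform(pedigree: Pedigree, row_order: list[str] | None = None,
                        ) -> MPHTransform:
    """Construct the n x (n+r) MPH transformation T and residual covariance TT'.

    ``row_order`` must list every hybrid and every parent exactly once
    (hybrids first then parents by convention); it defaults to that order
    with parents sorted by first appearance in the pedigree.
    """
    if row_order is None:
        parents = list(dict.fromkeys(list(pedigree.parent1_id) + list(pedigree.parent2_id)))
        row_order = list(pedigree.hybrid_id) + parents
    if len(set(row_order)) != len(row_order):
        raise PopulationError("duplicate ids in row_order")
    col = {gid: j for j, gid in enumerate(row_order)}
    missing = [g for g in list(pedigree.hybrid_id)
               + list(pedigree.parent1_id) + list(pedigree.parent2_id) if g not in col]
    if missing:
        raise PopulationError(f"ids missing from row_order: {sorted(set(missing))[:5]}")
    n = pedigree.n_hybrids
    data, rows, cols = [], [], []
    for f, (h, p1, p2) in enumerate(zip(pedigree.hybrid_id,
                                        pedigree.parent1_id, pedigree.parent2_id)):
        rows += [f, f, f]
        cols += [col[h], col[p1], col[p2]]
        data += [1.0, -0.5, -0.5]
    T = sparse.csr_matrix((data, (rows, cols)), shape=(n, len(row_order)))
    return MPHTransform(T=T, row_order=list(row_order))


def compute_mph(y_ori: np.ndarray | pd.Series, transform: MPHTransform) -> np.ndarray:
    """Mid-parent heterosis values ``T @ y_ori``.

    ``y_ori`` may be a plain vector aligned with ``transform.row_order`` or a
    pandas Series indexed by genotype id (reindexed and checked for gaps).
    """
    if isinstance(y_ori, pd.Series):
        y = y_ori.reindex(transform.row_order)
        if y.isna().any():
            missing = y.index[y.isna()].tolist()
            raise PopulationError(f"missing phenotypes for: {missing[:10]}")
        y = y.to_numpy(dtype=float)
    else:
        y = np.asarray(y_ori, dtype=float)
        if y.shape != (len(transform.row_order),):
            raise PopulationError("phenotype vector length does not match row order")
        if not np.all(np.isfinite(y)):
            raise PopulationError("non-finite phenotype values")
    return transform.T @ y


def pairwise_ld_r2(codes_i: np.ndarray, codes_j: np.ndarray) -> float:
    """Squared Pearson correlation of two additive code vectors (parent rows).

    Used for interval extension and merging; symmetric, 1 on the diagonal.
    """
    x = np.asarray(codes_i, dtype=float)
    y = np.asarray(codes_j, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise PopulationError("LD undefined: marker with zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# I/O: minimal tab-separated formats and biallelic VCF
# ---------------------------------------------------------------------------

def _read_genotypes_tsv(path) -> tuple[pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    required = ["marker_id", "chrom", "pos"]
    for c in required:
        if c not in df.columns:
            raise PopulationError(f"{path}: missing required column {c!r}")
    parent_cols = [c for c in df.columns if c not in required]
    if not parent_cols:
        raise PopulationError(f"{path}: no parent genotype columns")
    return df, parent_cols


def _read_genotypes_vcf(path) -> tuple[pd.DataFrame, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    parents = list(vcf.samples)
    records = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # code = number of REF alleles
        gts = var.genotypes  # [[a0, a1, phased], ...]
        codes = []
        for g in gts:
            a = [x for x in g[:-1] if x >= 0]
            if len(a) != 2:
                raise PopulationError(
                    f"missing genotype call at {var.CHROM}:{var.POS}; "
                    "imputation is out of scope")
            codes.append(2 - sum(a))
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        records.append([vid, var.CHROM, var.POS] + codes)
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP VCF records", n_skipped)
    df = pd.DataFrame(records, columns=["marker_id", "chrom", "pos"] + parents)
    return df, parents


def read_population(genotype_file, pedigree_file, phenotype_file=None,
                    fmt: str = "auto", maf: float = 0.05, strict: bool = True,
                    ) -> tuple[PopulationGenotypes, MarkerPanel,
                               MPHTransform, pd.Series | None]:
    """Load genotypes, pedigree and (optionally) phenotypes from disk.

    Returns the population, the MAF-filtered marker panel (sorted by
    chromosome and position), the MPH transform, and the phenotype Series
    (genotype id -> trait value) or None.  ``fmt`` is ``"tsv"``, ``"vcf"``
    or ``"auto"`` (by extension).
    """
    if fmt == "auto":
        fmt = "vcf" if str(genotype_file).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        gdf, parent_cols = _read_genotypes_vcf(genotype_file)
    elif fmt == "tsv":
        gdf, parent_cols = _read_genotypes_tsv(genotype_file)
    else:
        raise PopulationError(f"unknown genotype format {fmt!r}")

    gdf = gdf.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    codes = gdf[parent_cols].to_numpy(dtype=float).T  # r x p
    freq = codes.mean(axis=0) / 2.0
    keep = np.minimum(freq, 1 - freq) >= maf
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("MAF filter (threshold %.3g): removed %d of %d markers",
                    maf, n_drop, len(keep))
    gdf = gdf.loc[keep].reset_index(drop=True)
    codes = codes[:, keep]
    freq = freq[keep]
    if gdf.empty:
        raise PopulationError("no markers left after MAF filtering")

    pdf = pd.read_csv(pedigree_file, sep="\t", dtype=str)
    for c in ("hybrid_id", "parent1_id", "parent2_id"):
        if c not in pdf.columns:
            raise PopulationError(f"{pedigree_file}: missing column {c!r}")
    pedigree = Pedigree(pdf["hybrid_id"].tolist(), pdf["parent1_id"].tolist(),
                        pdf["parent2_id"].tolist())
    pop = infer_hybrid_genotypes(parent_cols, codes, pedigree, strict=strict)
    panel = MarkerPanel(gdf["marker_id"].tolist(), gdf["chrom"].tolist(),
                        gdf["pos"].to_numpy(), freq)
    transform = build_mph_transform(pedigree, pop.combined_ids)

    phenotypes = None
    if phenotype_file is not None:
        ydf = pd.read_csv(phenotype_file, sep="\t")
        cols = list(ydf.columns)
        if len(cols) < 2:
            raise PopulationError(f"{phenotype_file}: expected id and value columns")
        phenotypes = pd.Series(ydf[cols[1]].to_numpy(dtype=float),
                               index=ydf[cols[0]].astype(str).tolist())
    return pop, panel, transform, phenotypes


def write_population(pop: PopulationGenotypes, panel: MarkerPanel,
                     genotype_file, pedigree_file, phenotypes: pd.Series | None = None,
                     phenotype_file=None) -> None:
    """Write parent genotypes, pedigree and phenotypes as tab-separated files."""
    gdf = pd.DataFrame({"marker_id": panel.marker_id, "chrom": panel.chromosome,
                        "pos": panel.position_bp})
    for idx, pid in enumerate(pop.parent_ids):
        gdf[pid] = pop.parent_codes[idx].astype(int)
    gdf.to_csv(genotype_file, sep="\t", index=False)
    ped = pop.pedigree
    pd.DataFrame({"hybrid_id": ped.hybrid_id, "parent1_id": ped.parent1_id,
                  "parent2_id": ped.parent2_id}).to_csv(pedigree_file, sep="\t",
                                                        index=False)
    if phenotypes is not None:
        if phenotype_file is None:
            raise PopulationError("phenotype_file required when phenotypes given")
        pd.DataFrame({"genotype_id": phenotypes.index,
                      "value": phenotypes.to_numpy()}).to_csv(
            phenotype_file, sep="\t", index=False)
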