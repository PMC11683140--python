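"""Genotype containers, quality control, and marker relationship matrices.

Dosages are coded 0/1/2 copies of the counted allele (the ALT allele for VCF
input).  Missing calls are held as NaN until QC, which imputes them to the
marker mean (2p).  Three clone-by-clone covariance structures are built from
the filtered dosage matrix:

* additive ``G`` (VanRaden):       G = Z Z' / (2 * sum_i p_i (1 - p_i)),
  with Z the column-centered dosages (dosage - 2p);
* dominance ``D`` (Vitezica-type genotypic coding):  D = H H' / denom, where
  the H column for a marker maps dosage {0, 1, 2} to {-2p^2, 2pq, -2q^2};
  the default denominator is 2 * sum_i p_i q_i (1 - p_i q_i), with the
  classical sum_i (2 p_i q_i)^2 available as an option;
* Gaussian kernel ``K`` for RKHS:  K = exp(-h * Dist / median(Dist)), with
  Dist the Euclidean distance matrix of the (by default centered) dosages and
  the median taken over the strictly-upper-triangle entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix", "RelationshipMatrix", "load_genotypes", "qc_filter",
    "build_additive_grm", "build_dominance_grm", "build_gaussian_kernel",
]

#: diagonal ridge added to G/D before they enter any mixed-model solve
PSD_RIDGE = 1e-6


@dataclass
class MarkerMatrix:
    """Clone x marker allele-dosage matrix with frequency metadata."""

    clone_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float in [0, 2] ({0,1,2} for raw calls, fractional
    #                      values only from mean imputation) or NaN

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.clone_ids), len(self.marker_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        with np.errstate(invalid="ignore"):
            valid = np.isnan(self.dosages) | ((self.dosages >= 0.0)
                                              & (self.dosages <= 2.0))
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per marker, p = mean(dosage)/2 over non-missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def centered(self) -> np.ndarray:
        """Column-centered dosages Z = dosage - 2p (requires no missing)."""
        if self.has_missing:
            raise ValueError("missing dosages present; run qc_filter first")
        return self.dosages - 2.0 * self.allele_freq

    def subset_clones(self, clone_ids) -> "MarkerMatrix":
        idx = [self.clone_ids.index(c) for c in clone_ids]
        return MarkerMatrix(list(clone_ids), list(self.marker_ids), self.dosages[idx])

    # -- I/O ---------------------------------------------------------------

    def to_dosage_csv(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.marker_ids)
        df.insert(0, "clone", self.clone_ids)
        df.to_csv(path, index=False)

    def to_vcf(self, path) -> None:
        """Write a minimal biallelic VCF (GT field only, chromosome 1)."""
        finite = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("fractional (imputed) dosages cannot be written "
                             "as VCF genotype calls")
        p = self.allele_freq
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.clone_ids)) + "\n")
            gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, mid in enumerate(self.marker_ids):
                calls = ["./." if np.isnan(d) else gt_map[d] for d in self.dosages[:, j]]
                fh.write(f"1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")

    @classmethod
    def from_dosage_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "clone":
            raise ValueError("dosage CSV must have 'clone' as its first column")
        return cls(df["clone"].astype(str).tolist(),
                   df.columns[1:].tolist(),
                   df.iloc[:, 1:].to_numpy(dtype=float))

    @classmethod
    def from_vcf(cls, path) -> "MarkerMatrix":
        """Read biallelic GT calls from a VCF; the ALT allele is counted."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        clones = list(vcf.samples)
        cols, ids = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                raise ValueError(
                    f"multiallelic site {var.CHROM}:{var.POS} ({var.ID}); "
                    "only biallelic sites are supported")
            gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            col = np.where(gts == 0, 0.0,
                           np.where(gts == 1, 1.0,
                                    np.where(gts == 3, 2.0, np.nan)))
            cols.append(col)
            ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        vcf.close()
        if not cols:
            raise ValueError("no variants found in VCF")
        return cls(clones, ids, np.column_stack(cols))

    @classmethod
    def from_hapmap(cls, path) -> "MarkerMatrix":
        """Read a HapMap-format text file (tab-separated, diploid IUPAC or
        two-letter genotype calls, samples from column 12 on)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 12:
            raise ValueError("not a HapMap file: fewer than 12 columns")
        clones = df.columns[11:].tolist()
        ids = df.iloc[:, 0].tolist()
        cols = []
        for _, row in df.iterrows():
            ref, alt = str(row.iloc[1]).split("/")[:2]
            calls = []
            for g in row.iloc[11:]:
                g = str(g)
                if g in ("NN", "N", "--", "NA"):
                    calls.append(np.nan)
                    continue
                pair = (g[0], g[1]) if len(g) >= 2 else (g[0], g[0])
                calls.append(float(sum(1 for a in pair if a == alt)))
            cols.append(calls)
        return cls(clones, ids, np.array(cols, dtype=float).T)


@dataclass
class RelationshipMatrix:
    """Symmetric clone x clone covariance structure derived from markers."""

    kind: str  # additive | dominance | gaussian
    clone_ids: list[str]
    values: np.ndarray
    bandwidth_h: float | None = None
    denominator: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.clone_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square over clone_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def stabilized(self) -> np.ndarray:
        """Values with a small diagonal ridge, for use in solves."""
        return self.values + PSD_RIDGE * np.eye(self.n_clones)

    def subset(self, clone_ids) -> "RelationshipMatrix":
        idx = np.array([self.clone_ids.index(c) for c in clone_ids])
        return RelationshipMatrix(self.kind, list(clone_ids),
                                  self.values[np.ix_(idx, idx)],
                                  self.bandwidth_h, self.denominator)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.clone_ids,
                     columns=self.clone_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(kind, df.index.astype(str).tolist(), df.to_numpy(dtype=float))


# -- operations -------------------------------------------------------------


def load_genotypes(path, format: str = "dosage_csv") -> MarkerMatrix:
    """Load genotypes from ``vcf``, ``dosage_csv`` or ``hapmap`` files."""
    readers = {"vcf": MarkerMatrix.from_vcf,
               "dosage_csv": MarkerMatrix.from_dosage_csv,
               "hapmap": MarkerMatrix.from_hapmap}
    if format not in readers:
        raise ValueError(f"unknown genotype format '{format}'")
    return readers[format](path)


def qc_filter(m: MarkerMatrix, maf_threshold: float = 0.01) -> MarkerMatrix:
    """Drop markers with MAF strictly below the threshold; impute missing to 2p.

    MAF is min(p, 1-p) computed on non-missing calls.  Imputation happens
    after filtering, so reported frequencies are post-imputation column means.
    """
    if not 0.0 <= maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5]")
    p = m.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_threshold
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"all {m.n_markers} markers removed at MAF < {maf_threshold}")
    if n_removed:
        removed = [mid for mid, k in zip(m.marker_ids, keep) if not k]
        logger.info("qc_filter removed %d/%d markers below MAF %g: %s",
                    n_removed, m.n_markers, maf_threshold,
                    ", ".join(map(str, removed[:20])) + ("..." if n_removed > 20 else ""))
    dos = m.dosages[:, keep].copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.where(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]
    return MarkerMatrix(list(m.clone_ids),
                        [mid for mid, k in zip(m.marker_ids, keep) if k],
                        dos)


def _check_clean(m: MarkerMatrix):
    if m.has_missing:
        raise ValueError("missing dosages present; run qc_filter first")


def build_additive_grm(m: MarkerMatrix) -> RelationshipMatrix:
    """VanRaden additive genomic relationship matrix."""
    _check_clean(m)
    p = m.allele_freq
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: additive GRM denominator is zero")
    Z = m.dosages - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix("additive", list(m.clone_ids), 0.5 * (G + G.T),
                              denominator=denom)


def dominance_design(m: MarkerMatrix) -> np.ndarray:
    """Genotypic dominance coding: dosage {0,1,2} -> {-2p^2, 2pq, -2q^2}.

    The coding is defined on integer genotype classes; fractional imputed
    dosages are assigned to the nearest class.
    """
    _check_clean(m)
    p = m.allele_freq
    q = 1.0 - p
    d = np.rint(m.dosages)
    return np.where(d == 1.0, 2.0 * p * q,
                    np.where(d == 0.0, -2.0 * p ** 2, -2.0 * q ** 2))


def build_dominance_grm(m: MarkerMatrix, denominator: str = "printed") -> RelationshipMatrix:
    """Dominance genomic relationship matrix D = H H' / denom.

    ``denominator='printed'`` uses 2 * sum(p q (1 - p q)); ``'vitezica'``
    uses the classical sum((2 p q)^2).
    """
    H = dominance_design(m)
    p = m.allele_freq
    q = 1.0 - p
    if denominator == "printed":
        denom = float(2.0 * np.sum(p * q * (1.0 - p * q)))
    elif denominator == "vitezica":
        denom = float(np.sum((2.0 * p * q) ** 2))
    else:
        raise ValueError("denominator must be 'printed' or 'vitezica'")
    if denom <= 0.0:
        raise ValueError("dominance GRM denominator is zero (no heterozygosity)")
    D = (H @ H.T) / denom
    return RelationshipMatrix("dominance", list(m.clone_ids), 0.5 * (D + D.T),
                              denominator=denom)


def build_gaussian_kernel(m: MarkerMatrix, h: float = 1.0,
                          coding: str = "centered") -> RelationshipMatrix:
    """Gaussian kernel K = exp(-h * Dist / median(Dist)) over clone pairs."""
    _check_clean(m)
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    if m.n_clones < 2:
        raise ValueError("at least two clones required for a kernel")
    if coding == "centered":
        M = m.centered()
    elif coding == "raw":
        M = m.dosages
    else:
        raise ValueError("coding must be 'centered' or 'raw'")
    d = pdist(M, metric="euclidean")
    med = float(np.median(d))
    if med <= 0.0:
        raise ValueError("all pairwise distances are zero; kernel scale undefined")
    K = np.exp(-h * squareform(d) / med)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix("gaussian", list(m.clone_ids), K, bandwidth_h=h)
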