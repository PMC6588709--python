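"""SNP QC, imputation and genomic relationship matrices.

The genomic matrix follows VanRaden's first method: dosages centered by
twice the observed allele frequency, cross-product scaled by
``2 * sum_j p_j (1 - p_j)``.  ``rescale_g`` puts G on the pedigree base by
matching the mean diagonal and the overall mean of the pedigree matrix on
the genotyped subset; ``blend`` forms ``K = w*A + (1-w)*Gs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix, check_alignment

logger = logging.getLogger(__name__)


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix; missing cells are NaN."""

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(i) for i in self.line_ids]
        self.marker_ids = [str(i) for i in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise GenotypeError(f"dosages must be 0/1/2/missing; found {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_freqs(self) -> np.ndarray:
        """Per-marker frequency of the counted allele over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())


def read_genotypes_csv(path: str) -> GenotypeMatrix:
    """CSV matrix: first column line id, header row marker ids, cells 0/1/2/NA."""
    frame = pd.read_csv(path, index_col=0)
    return GenotypeMatrix(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(dtype=float),
    )


def write_genotypes_csv(geno: GenotypeMatrix, path: str) -> None:
    frame = pd.DataFrame(geno.dosages, index=geno.line_ids, columns=geno.marker_ids)
    # keep integral dosages integral in the file
    frame.to_csv(path, index_label="line_id", float_format="%g")


def read_genotypes_vcf(path: str) -> GenotypeMatrix:
    """Read dosages (ALT-allele counts) from a VCF; multi-allelic records skipped."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    line_ids = [str(s) for s in vcf.samples]
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        gt = variant.gt_types.astype(float)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        name = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(str(name))
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped)
    if not rows:
        raise GenotypeError(f"no usable bi-allelic records in {path}")
    return GenotypeMatrix(line_ids, marker_ids, np.column_stack(rows))


def read_genotypes(path: str) -> GenotypeMatrix:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_genotypes_vcf(path)
    return read_genotypes_csv(path)


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.025,
    max_missing: float = 0.20,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with MAF below ``maf_min`` or missingness above ``max_missing``.

    Frequencies are computed on non-missing calls only, before any
    imputation.  Returns the filtered matrix and a per-marker report with
    columns ``marker_id, maf, missing_frac, removed_reason``.
    """
    with np.errstate(invalid="ignore"):
        p = geno.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    miss = geno.missing_fraction()

    reasons = np.full(geno.n_markers, "", dtype=object)
    all_missing = np.isnan(p)
    reasons[all_missing | (maf < maf_min)] = "maf"
    reasons[miss > max_missing] = np.where(
        reasons[miss > max_missing] == "maf", "maf;missingness", "missingness"
    )
    keep = reasons == ""
    report = pd.DataFrame(
        {
            "marker_id": geno.marker_ids,
            "maf": maf,
            "missing_frac": miss,
            "removed_reason": reasons,
        }
    )
    if not keep.any():
        raise GenotypeError("QC removed every marker")
    kept = GenotypeMatrix(
        geno.line_ids,
        [m for m, k in zip(geno.marker_ids, keep) if k],
        geno.dosages[:, keep],
    )
    logger.info("QC retained %d of %d markers", kept.n_markers, geno.n_markers)
    return kept, report


def impute_missing(geno: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing dosages by sampling from the marginal allele distribution.

    Each missing cell is an independent Binomial(2, p_j) draw with p_j the
    observed allele frequency of marker j.  Deterministic given ``seed``.
    """
    if not geno.has_missing():
        return geno
    rng = np.random.default_rng(seed)
    dos = geno.dosages.copy()
    p = geno.allele_freqs()
    if np.isnan(p).any():
        bad = [m for m, f in zip(geno.marker_ids, p) if np.isnan(f)]
        raise GenotypeError(f"markers entirely missing (run qc_filter first): {bad[:5]}")
    mask = np.isnan(dos)
    rows, cols = np.nonzero(mask)
    dos[rows, cols] = rng.binomial(2, p[cols]).astype(float)
    return GenotypeMatrix(geno.line_ids, geno.marker_ids, dos)


def vanraden_g(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``G = W W' / (2 * sum_j p_j (1-p_j))`` with ``W`` the dosage matrix
    centered by ``2 p_j`` and ``p_j`` the observed frequencies of the
    genotyped set itself.
    """
    if geno.has_missing():
        raise GenotypeError("impute missing dosages before computing G")
    p = geno.allele_freqs()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise GenotypeError("all markers monomorphic; G denominator is zero")
    w = geno.dosages - 2.0 * p
    return RelationshipMatrix(geno.line_ids, (w @ w.T) / denom, kind="G")


@dataclass(frozen=True)
class RescaleCoefficients:
    """Affine coefficients of ``Gs = offset_a + scale_b * G``."""

    offset_a: float
    scale_b: float


def rescale_g(
    G: RelationshipMatrix,
    A_gg: RelationshipMatrix,
    variant: str = "all-elements",
) -> tuple[RelationshipMatrix, RescaleCoefficients]:
    """Rescale G to the pedigree base: ``Gs = a + b*G``.

    ``a`` and ``b`` solve the 2x2 system equating (i) the mean diagonals
    (average inbreeding) and (ii) the overall mean relationships of ``Gs``
    and ``A_gg`` over the genotyped lines.  ``variant='offdiag'`` uses the
    off-diagonal mean instead of the all-elements mean in (ii).
    """
    if variant not in ("all-elements", "offdiag"):
        raise ValueError(f"unknown rescaling variant {variant!r}")
    check_alignment(G, A_gg)
    a_vals = A_gg.aligned_values(G.ids)
    g_vals = G.values
    n = G.n
    dg, da = float(np.mean(np.diag(g_vals))), float(np.mean(np.diag(a_vals)))
    if variant == "all-elements":
        mg, ma = float(np.mean(g_vals)), float(np.mean(a_vals))
    else:
        off = ~np.eye(n, dtype=bool)
        mg, ma = float(np.mean(g_vals[off])), float(np.mean(a_vals[off]))
    if abs(dg - mg) < 1e-12:
        raise GenotypeError(
            "rescaling system is singular: mean(diag G) equals the overall mean of G"
        )
    scale_b = (da - ma) / (dg - mg)
    if scale_b <= 0.0:
        raise GenotypeError(f"rescaling slope must be positive, got {scale_b:g}")
    offset_a = da - scale_b * dg
    gs = RelationshipMatrix(list(G.ids), offset_a + scale_b * g_vals, kind="Gs")
    return gs, RescaleCoefficients(offset_a=offset_a, scale_b=scale_b)


def blend(
    A: RelationshipMatrix, Gs: RelationshipMatrix, w: float
) -> RelationshipMatrix:
    """Blended kinship ``K = w*A + (1-w)*Gs`` over the shared (genotyped) ids."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"blending weight must lie in [0, 1], got {w}")
    check_alignment(A, Gs)
    a_vals = A.aligned_values(Gs.ids)
    return RelationshipMatrix(
        list(Gs.ids), w * a_vals + (1.0 - w) * Gs.values, kind="K"
    )


def ensure_pd(K: RelationshipMatrix, eps: float = 1e-8) -> RelationshipMatrix:
    """Diagonal-load ``K`` so its minimum eigenvalue is at least ``eps``."""
    lam_min = K.min_eigenvalue()
    if lam_min >= eps:
        return K
    bump = eps - lam_min
    logger.warning("PD repair on %s matrix: adding %.3e to the diagonal", K.kind, bump)
    return RelationshipMatrix(
        list(K.ids), K.values + bump * np.eye(K.n), kind=K.kind
    )
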