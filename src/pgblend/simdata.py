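"""Synthetic breeding-program generator.

Produces the three inputs the analysis pipeline consumes — a multi-
generation pedigree ending in full-sib line families, gene-dropped unlinked
SNP genotypes, and line-level adjusted means (BLUEs) with heteroscedastic
standard errors — together with the generating truth so estimators can be
validated.

The trait is additive with a marker-captured part ``m = W beta`` (``W``
centered dosages, effects drawn so the marker-borne variance is
``(1 - w_true) * sigma2_g``) and a residual polygenic part
``a ~ N(0, A * w_true * sigma2_g)`` drawn through the pedigree, so that
``g = m + a`` matches the structure the blended and two-kernel models
assume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix
from .pedigree import Pedigree, full_sib_families, numerator_relationship_matrix

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults mirror the target application at roughly 70% size: 60 full-sib
    families of 8 lines (480 lines) descending from 40 founders through 4
    generations of random mating, 1,000 unlinked SNPs.
    """

    n_founders: int = 40
    n_generations: int = 4
    n_families: int = 60
    sibs_per_family: int = 8
    n_markers: int = 1000
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    w_true: float = 0.5
    h2_true: float = 0.6
    mu_true: float = 10.0
    se_range: tuple[float, float] = (0.5, 1.5)
    missing_rate: float = 0.02
    selfing_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_true <= 1.0:
            raise ValueError(f"w_true must lie in [0, 1], got {self.w_true}")
        if not 0.0 < self.h2_true < 1.0:
            raise ValueError(f"h2_true must lie in (0, 1), got {self.h2_true}")
        if self.se_range[0] <= 0:
            raise ValueError("se_range lower bound must be positive")
        lo, hi = self.founder_freq_range
        if not (0.05 <= lo < hi <= 0.95):
            raise ValueError("founder_freq_range must be within (0.05, 0.95)")
        if self.n_founders < 4:
            raise ValueError("need at least 4 founders")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class SimTruth:
    """Generating truth for the line cohort."""

    line_ids: list[str]
    g_true: np.ndarray
    m_true: np.ndarray
    a_true: np.ndarray
    marker_effects: np.ndarray
    sigma2_g: float
    realized_polygenic_share: float = field(init=False)

    def __post_init__(self) -> None:
        var_g = float(np.var(self.g_true))
        self.realized_polygenic_share = (
            float(np.var(self.a_true)) / var_g if var_g > 0 else float("nan")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line_id": self.line_ids,
                "g_true": self.g_true,
                "m_true": self.m_true,
                "a_true": self.a_true,
            }
        )


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Random-mating ancestor generations topped by full-sib line families.

    The returned pedigree carries the line cohort in ``line_ids``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    records: list[tuple[str, str | None, str | None]] = []
    current = [f"F{i:04d}" for i in range(cfg.n_founders)]
    records.extend((f, None, None) for f in current)

    for gen in range(1, cfg.n_generations + 1):
        nxt = []
        for j in range(cfg.n_founders):
            s, d = rng.choice(len(current), size=2, replace=False)
            ind = f"G{gen}_{j:04d}"
            records.append((ind, current[s], current[d]))
            nxt.append(ind)
        current = nxt

    n_parents = len(current)
    max_pairs = n_parents * (n_parents - 1) // 2
    if cfg.n_families > max_pairs:
        raise ValueError(
            f"{cfg.n_families} families requested but only {max_pairs} "
            f"distinct parent pairs available"
        )
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < cfg.n_families:
        s, d = rng.choice(n_parents, size=2, replace=False)
        pairs.add((min(s, d), max(s, d)))
    line_ids: list[str] = []
    for fam, (s, d) in enumerate(sorted(pairs)):
        fam_parents = (current[s], current[d])
        for sib in range(cfg.sibs_per_family):
            base = f"L{fam:03d}_{sib:02d}"
            prev = None
            # optional selfing chain toward inbred lines; the final name is
            # the line itself so genotype/phenotype ids stay stable
            for sg in range(cfg.selfing_generations):
                name = f"{base}_s{sg}"
                if prev is None:
                    records.append((name, *fam_parents))
                else:
                    records.append((name, prev, prev))
                prev = name
            if prev is None:
                records.append((base, *fam_parents))
            else:
                records.append((base, prev, prev))
            line_ids.append(base)
    return Pedigree(records, line_ids=line_ids)


def gene_drop(
    ped: Pedigree, cfg: SimConfig, mask_missing: bool = True
) -> GenotypeMatrix:
    """Drop unlinked biallelic markers through the pedigree.

    Founder alleles are Bernoulli draws at per-marker frequencies sampled
    uniformly from ``founder_freq_range``; every offspring receives one
    allele sampled at random from each parent's two alleles, per marker.
    With ``mask_missing`` a fraction ``missing_rate`` of line-cohort calls
    is set missing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    m = cfg.n_markers
    freqs = rng.uniform(*cfg.founder_freq_range, size=m)
    order = {ind: k for k, (ind, _, _) in enumerate(ped.records)}
    alleles = np.zeros((ped.n, m, 2), dtype=np.int8)
    for k, (ind, sire, dam) in enumerate(ped.records):
        for slot, parent in enumerate((sire, dam)):
            if parent is None:
                alleles[k, :, slot] = rng.random(m) < freqs
            else:
                picks = rng.integers(2, size=m)
                alleles[k, :, slot] = alleles[order[parent], np.arange(m), picks]

    line_ids = ped.line_ids if ped.line_ids is not None else ped.ids
    rows = [order[i] for i in line_ids]
    dosages = alleles[rows].sum(axis=2).astype(float)
    if mask_missing and cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
    marker_ids = [f"M{j:05d}" for j in range(m)]
    return GenotypeMatrix(list(line_ids), marker_ids, dosages)


def simulate_phenotypes(
    ped: Pedigree, geno: GenotypeMatrix, cfg: SimConfig
):
    """Line BLUEs with heteroscedastic SEs plus the generating truth.

    ``geno`` must be the complete (pre-masking) line-cohort genotypes so
    the truth is unaffected by missingness.  The additive variance is set
    to ``h2_true / (1 - h2_true) * mean(se^2)`` so the heritability of line
    means matches ``h2_true`` in expectation.
    """
    from .blup import PhenotypeTable  # local import to avoid a cycle

    if geno.has_missing():
        raise ValueError("simulate_phenotypes needs complete (pre-masking) genotypes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 37]))
    line_ids = list(geno.line_ids)
    n = len(line_ids)

    ses = rng.uniform(*cfg.se_range, size=n)
    sigma2_g = cfg.h2_true / (1.0 - cfg.h2_true) * float(np.mean(ses**2))

    # marker-captured part
    p = geno.allele_freqs()
    het = 2.0 * float(np.sum(p * (1.0 - p)))
    if cfg.w_true < 1.0:
        sigma2_beta = (1.0 - cfg.w_true) * sigma2_g / het
        beta = rng.normal(0.0, np.sqrt(sigma2_beta), size=geno.n_markers)
    else:
        beta = np.zeros(geno.n_markers)
    w_mat = geno.dosages - 2.0 * p
    m_true = w_mat @ beta

    # residual polygenic part through the pedigree
    if cfg.w_true > 0.0:
        a_mat = numerator_relationship_matrix(ped, subset_ids=line_ids).values
        lam_min = float(np.linalg.eigvalsh(a_mat)[0])
        if lam_min < 1e-10:
            a_mat = a_mat + (1e-10 - lam_min) * np.eye(n)
        chol = np.linalg.cholesky(a_mat * (cfg.w_true * sigma2_g))
        a_true = chol @ rng.standard_normal(n)
    else:
        a_true = np.zeros(n)

    g_true = m_true + a_true
    e = rng.normal(0.0, ses)
    blues = cfg.mu_true + g_true + e

    pheno = PhenotypeTable(line_ids, blues, ses, trait="sim_trait")
    truth = SimTruth(
        line_ids=line_ids,
        g_true=g_true,
        m_true=m_true,
        a_true=a_true,
        marker_effects=beta,
        sigma2_g=sigma2_g,
    )
    return pheno, truth


def simulate_dataset(cfg: SimConfig):
    """Convenience orchestration: pedigree, observed + complete genotypes,
    phenotypes and truth in one call."""
    ped = simulate_pedigree(cfg)
    geno_complete = gene_drop(ped, cfg, mask_missing=False)
    if cfg.missing_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 53]))
        dosages = geno_complete.dosages.copy()
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
        geno_observed = GenotypeMatrix(
            list(geno_complete.line_ids), list(geno_complete.marker_ids), dosages
        )
    else:
        geno_observed = geno_complete
    pheno, truth = simulate_phenotypes(ped, geno_complete, cfg)
    return ped, geno_observed, geno_complete, pheno, truth


def line_families(ped: Pedigree) -> dict[tuple, list[str]]:
    ids = ped.line_ids if ped.line_ids is not None else ped.ids
    return full_sib_families(ped, ids)
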