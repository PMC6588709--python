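# pgblend

Blended pedigree–genomic relationship matrices and BLUP prediction for
structured breeding populations.

`pgblend` implements a complete genomic-prediction workflow for inbred-line
breeding programs where line means (BLUEs) with heteroscedastic standard
errors are the phenotypic input:

- **pedigree** — pedigree parsing/validation and the numerator relationship
  matrix **A** (tabular method, with inbreeding and full-sib family grouping);
- **kinship** — SNP QC (MAF / missingness), marginal-frequency imputation,
  the VanRaden method-1 genomic matrix **G**, rescaling
  **Gs** = a + b·**G** to the pedigree base (matching mean inbreeding and
  mean relationship), and the blended matrix **K** = w·**A** + (1−w)·**Gs**;
- **blup** — REML variance-component estimation and BLUP under
  `y = 1μ + Zg + e` with residual covariance `σ²ₑ·diag(se²)`, for a single
  kinship (A-BLUP / G-BLUP / K-BLUP) or for two independent kernels
  (AG-BLUP, `g = m + a`), plus an independent SNP-BLUP (ridge) oracle;
- **crossval** — fivefold cross-validation with within-family (W-fam) and
  among-family (A-fam) splitting, a weight-grid sweep reusing identical fold
  plans across all models, and optimal-weight selection;
- **evaluation** — predictive ability (Pearson r), empirical bias slope,
  MSEP (two definitions), and the Hotelling–Williams t test for dependent
  correlations;
- **simdata** — a synthetic breeding-program generator: multi-generation
  random-mating pedigree topped by full-sib families, gene-dropped unlinked
  SNPs, additive values split into marker-captured and residual polygenic
  parts, and heteroscedastic line BLUEs with known truth.

## Quick start (Python)

```python
import pgblend as pg

cfg = pg.SimConfig(seed=1)                      # 60 families x 8 sibs, 1000 SNPs
ped, geno, _, pheno, truth = pg.simulate_dataset(cfg)

A = pg.numerator_relationship_matrix(ped).restrict(ped.line_ids)
geno_qc, report = pg.qc_filter(geno)            # MAF >= 2.5%, missing <= 20%
G = pg.vanraden_g(pg.impute_missing(geno_qc, seed=2))
Gs, coef = pg.rescale_g(G, A)                   # put G on the pedigree base

fit = pg.fit_two_kernel(pheno, pg.ensure_pd(A), pg.ensure_pd(Gs))
print(pg.heritability(fit.vc), pg.ml_weight_from_agblup(fit))

families = pg.full_sib_families(ped, ped.line_ids)
sweep = pg.run_cv(pheno, A, Gs, families,
                  grid=[0, 0.2, 0.4, 0.6, 0.8, 1.0], n_reps=20, base_seed=7)
print(sweep.summary())
print(pg.select_optimal_w(sweep, "W-fam"))
```

## Command line

```bash
pgblend simulate --seed 1 --out runs/sim
pgblend kinship  --pedigree runs/sim/pedigree.csv --genotypes runs/sim/genotypes.csv \
                 --w 0.5 --out runs/kin
pgblend fit      --pedigree runs/sim/pedigree.csv --genotypes runs/sim/genotypes.csv \
                 --phenotypes runs/sim/phenotypes.tsv --model AG-BLUP --out runs/fit
pgblend cv       --pedigree runs/sim/pedigree.csv --genotypes runs/sim/genotypes.csv \
                 --phenotypes runs/sim/phenotypes.tsv \
                 --grid 0,0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,1 --reps 20 --out runs/cv
pgblend evaluate --records runs/cv/cv_records.tsv --out runs/eval
```

Useful flags: `--fixed-r` pins the residual scale so the residual covariance
is exactly `diag(se²)`; `--rescale {all-elements,offdiag}` chooses the mean
used in the Gs system; `--msep {diff,resid}` selects the MSEP definition;
`--scheme {wfam,afam,both}` selects the CV scheme. Every output directory
contains a `run_manifest.json` with the resolved configuration.

## File formats

| Data | Format |
| --- | --- |
| Pedigree | CSV/TSV, header `id,sire,dam`; `0`/empty = unknown parent |
| Genotypes | CSV matrix (rows = lines, header = markers, cells 0/1/2/NA) or VCF (ALT dosage; multi-allelic records skipped) |
| Phenotypes | TSV, header `line_id trait blue se` |
| Relationship matrices | square CSV with id row/column, 12 significant digits |

## Tests and acceptance report

```bash
python -m pytest -q tests/            # unit + property + acceptance suites, ~3 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria (one test each):
exact equivalence of the tabular A matrix with a path-counting oracle,
G-BLUP ≡ SNP-BLUP and K-BLUP ≡ AG-BLUP equivalences at matched variance
components, rescaling exactness, parameter recovery and weight-sweep shape
on simulated data, calibration of the Hotelling–Williams test, CV fold
structure, and QC exactness. `scripts/acceptance.py` re-runs a condensed
end-to-end verification and writes its JSON report (empty mapping — this
study defines no reproducible numeric targets; the source data are
proprietary).

## Caveats

- The optimal blending weight is selected on the same cross-validation it is
  reported from (mirroring the intended analysis); no nested CV is done.
- Simulated markers are unlinked; family structure, not LD decay, is what
  makes the genomic matrix informative in the generator.
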