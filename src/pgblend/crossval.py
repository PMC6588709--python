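"""Family-structured cross-validation and the blending-weight sweep.

Two splitting schemes are supported:

* ``W-fam`` — within-family prediction: each full-sib family is dealt
  across all folds, so every validation set contains close relatives of
  the training set.
* ``A-fam`` — among-family prediction: whole families are dealt to folds,
  so validation lines belong to families absent from the training set.

Fold plans depend only on ``(base_seed, scheme, replicate)``; the same plan
is reused for every weight on the grid and for the two-kernel competitor,
so all models see identical training/validation splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blup import BlupFit, PhenotypeTable, fit_single_kernel, fit_two_kernel
from .evaluation import quality_metrics
from .kinship import blend, ensure_pd
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

SCHEMES = ("W-fam", "A-fam")

AGBLUP_TAG = "AG-BLUP"


@dataclass(frozen=True)
class FoldPlan:
    scheme: str
    replicate: int
    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def all_ids(self) -> set[str]:
        return {i for fold in self.folds for i in fold}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (line, self.scheme, self.replicate, fold_idx)
            for fold_idx, fold in enumerate(self.folds)
            for line in fold
        ]
        return pd.DataFrame(rows, columns=["line_id", "scheme", "replicate", "fold"])


def _fold_seed(base_seed: int, scheme: str, replicate: int) -> int:
    """Stable per-(scheme, replicate) seed so every model sees identical folds."""
    ss = np.random.SeedSequence([int(base_seed), SCHEMES.index(scheme), int(replicate)])
    return int(ss.generate_state(1)[0])


def make_folds(
    scheme: str,
    families: dict[tuple, list[str]],
    k: int = 5,
    replicate: int = 0,
    base_seed: int = 0,
) -> FoldPlan:
    """Build one k-fold plan under the given scheme.

    W-fam: lines within each family are shuffled then dealt round-robin to
    folds starting at a random offset (folds get floor(n_f/k) or
    ceil(n_f/k) lines of each family).  A-fam: whole families are shuffled
    and dealt round-robin, so no family is split across folds.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    seed = _fold_seed(base_seed, scheme, replicate)
    rng = np.random.default_rng(seed)
    fam_keys = sorted(families, key=str)
    folds: list[list[str]] = [[] for _ in range(k)]

    if scheme == "A-fam":
        if len(fam_keys) < k:
            raise ValueError(
                f"A-fam needs at least {k} families, got {len(fam_keys)}"
            )
        for slot, fi in enumerate(rng.permutation(len(fam_keys))):
            folds[slot % k].extend(sorted(families[fam_keys[fi]]))
    else:
        for key in fam_keys:
            members = sorted(families[key])
            order = rng.permutation(len(members))
            offset = int(rng.integers(k))
            for slot, mi in enumerate(order):
                folds[(slot + offset) % k].append(members[mi])

    return FoldPlan(
        scheme=scheme,
        replicate=replicate,
        folds=tuple(tuple(f) for f in folds),
        seed=seed,
    )


@dataclass
class SweepResult:
    """Tidy per-(scheme, model, replicate) metrics plus summaries."""

    records: pd.DataFrame
    grid: tuple[float, ...]
    schemes: tuple[str, ...]
    n_reps: int
    k: int
    base_seed: int
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        grp = self.records.groupby(["scheme", "model"], sort=False)
        out = grp.agg(
            r_pa_mean=("r_pa", "mean"),
            r_pa_sd=("r_pa", "std"),
            bias_mean=("bias_slope", "mean"),
            bias_sd=("bias_slope", "std"),
            msep_mean=("msep", "mean"),
            msep_sd=("msep", "std"),
            n_converged=("r_pa", "count"),
        ).reset_index()
        return out

    def weight_rows(self, scheme: str) -> pd.DataFrame:
        sub = self.records[
            (self.records["scheme"] == scheme) & self.records["w"].notna()
        ]
        return sub


def select_optimal_w(sweep: SweepResult, scheme: str) -> float:
    """Grid weight maximizing mean predictive ability; ties go to the smallest w."""
    sub = sweep.weight_rows(scheme)
    if sub["w"].nunique() < 2:
        raise ValueError("need at least 2 grid points to select a weight")
    means = sub.groupby("w")["r_pa"].mean().dropna()
    if means.empty:
        raise ValueError(f"all metrics missing for scheme {scheme!r}")
    best = means.max()
    return float(min(w for w, m in means.items() if m == best))


def _predict_fold(
    fit: BlupFit, vs_ids: tuple[str, ...]
) -> dict[str, float]:
    return {i: fit.gebv[i] for i in vs_ids}


def run_cv(
    pheno: PhenotypeTable,
    A: RelationshipMatrix,
    Gs: RelationshipMatrix,
    families: dict[tuple, list[str]],
    grid: list[float],
    schemes: tuple[str, ...] = SCHEMES,
    k: int = 5,
    n_reps: int = 20,
    base_seed: int = 0,
    include_agblup: bool = True,
    fixed_r: bool = False,
) -> SweepResult:
    """Full cross-validated sweep of the blending weight.

    For every (scheme, replicate) one fold plan is built and reused across
    the whole grid and the two-kernel competitor.  Validation BLUEs are
    withheld entirely from training; metrics are computed per replicate on
    the validation predictions pooled over the k folds.
    """
    grid = sorted(set(float(w) for w in grid))
    if any(w < 0 or w > 1 for w in grid):
        raise ValueError("grid weights must lie in [0, 1]")
    phenotyped = set(pheno.line_ids)
    cv_families = {
        key: [l for l in lines if l in phenotyped]
        for key, lines in families.items()
    }
    cv_families = {key: lines for key, lines in cv_families.items() if lines}

    a_lines = ensure_pd(A.restrict(pheno.line_ids))
    gs_lines = ensure_pd(Gs.restrict(pheno.line_ids))
    k_mats = {w: ensure_pd(blend(a_lines, gs_lines, w)) for w in grid}

    blues = dict(zip(pheno.line_ids, pheno.blues))
    rows: list[dict] = []
    failures: list[dict] = []

    for scheme in schemes:
        for rep in range(1, n_reps + 1):
            plan = make_folds(scheme, cv_families, k=k, replicate=rep, base_seed=base_seed)
            models: list[tuple[str, float | None]] = [(f"w={w:g}", w) for w in grid]
            if include_agblup:
                models.append((AGBLUP_TAG, None))
            pooled: dict[str, dict[str, float]] = {tag: {} for tag, _ in models}
            failed: set[str] = set()
            for fold in plan.folds:
                if not fold:
                    continue
                ts_pheno = pheno.drop(set(fold))
                for tag, w in models:
                    if tag in failed:
                        continue
                    try:
                        if w is None:
                            fit = fit_two_kernel(
                                ts_pheno, a_lines, gs_lines, fixed_r=fixed_r
                            )
                        else:
                            fit = fit_single_kernel(
                                ts_pheno, k_mats[w], fixed_r=fixed_r, model_tag=tag
                            )
                        if not fit.converged:
                            raise RuntimeError("REML did not converge")
                    except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                        logger.warning(
                            "%s rep %d %s failed: %s", scheme, rep, tag, exc
                        )
                        failed.add(tag)
                        failures.append(
                            {
                                "scheme": scheme,
                                "replicate": rep,
                                "model": tag,
                                "error": str(exc),
                            }
                        )
                        continue
                    pooled[tag].update(_predict_fold(fit, fold))
            for tag, w in models:
                if tag in failed:
                    rows.append(
                        {
                            "scheme": scheme,
                            "model": tag,
                            "w": w,
                            "replicate": rep,
                            "r_pa": np.nan,
                            "bias_slope": np.nan,
                            "msep": np.nan,
                            "msep_residual": np.nan,
                            "n": 0,
                        }
                    )
                    continue
                vs_ids = sorted(pooled[tag])
                pred = np.array([pooled[tag][i] for i in vs_ids])
                real = np.array([blues[i] for i in vs_ids])
                qm = quality_metrics(pred, real)
                rows.append(
                    {
                        "scheme": scheme,
                        "model": tag,
                        "w": w,
                        "replicate": rep,
                        "r_pa": qm.r_pa,
                        "bias_slope": qm.bias_slope,
                        "msep": qm.msep,
                        "msep_residual": qm.msep_residual,
                        "n": qm.n,
                    }
                )

    return SweepResult(
        records=pd.DataFrame(rows),
        grid=tuple(grid),
        schemes=tuple(schemes),
        n_reps=n_reps,
        k=k,
        base_seed=base_seed,
        diagnostics=pd.DataFrame(failures),
    )
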