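"""Random cross-validation for incomplete field trials, and the APC/MAAPE
accuracy metrics.

The partition scheme mimics the prediction problem breeders face when some
lines are evaluated in some, but not all, target environments: per
partition, m = round(p_testing * N) lines are drawn (with replacement if
J < m, without otherwise) and for each drawn line one environment is picked
uniformly; those cells form the testing set and everything else trains.
The same partitions are applied to every model being compared.

APC is the Pearson correlation between observed and predicted test values,
averaged over partitions; MAAPE is the mean of arctan(|(y - yhat)/y|) in
radians, bounded in [0, pi/2] and finite at y = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenomicRelationship, PhenotypeTable
from .gblup import GBLUPGxE
from .stacking import BMORS

__all__ = ["CVConfig", "CVPartition", "make_partitions", "pearson", "maape",
           "run_cv", "cells_to_training_mask"]


@dataclass
class CVConfig:
    """Settings of the random cross-validation."""

    p_testing: float = 0.2
    n_partitions: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_testing < 1.0:
            raise ValueError("p_testing must be in (0, 1)")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")


@dataclass
class CVPartition:
    """One train/test split over the N grid cells."""

    test_cells: set
    train_cells: set


def make_partitions(pheno: PhenotypeTable, cfg: CVConfig,
                    rng: np.random.Generator | None = None) -> list:
    """Draw ``cfg.n_partitions`` independent random train/test splits.

    m = round(p_testing * N) lines are sampled — with replacement if
    J < m, without replacement otherwise — and one environment is picked
    uniformly per drawn line.  Duplicate cells collapse, so the testing set
    may hold fewer than m cells under with-replacement sampling.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    N = pheno.n_cells
    J, I = pheno.n_lines, pheno.n_envs
    m = round(cfg.p_testing * N)
    if m == 0:
        raise ValueError("p_testing too small: empty testing set")
    replace = J < m
    all_cells = set(pheno.cells())
    partitions = []
    for _ in range(cfg.n_partitions):
        lines = rng.choice(J, size=m, replace=replace)
        envs = rng.integers(0, I, size=m)
        test = {(pheno.line_ids[j], pheno.env_ids[i])
                for j, i in zip(lines, envs)}
        partitions.append(CVPartition(test, all_cells - test))
    return partitions


def cells_to_training_mask(pheno: PhenotypeTable, test_cells) -> np.ndarray:
    """Boolean vector over grid cells: True where the cell may train."""
    mask = np.ones(pheno.n_cells, dtype=bool)
    for line, env in test_cells:
        mask[pheno.cell_index(line, env)] = False
    return mask


def pearson(observed, predicted) -> float:
    """Sample Pearson correlation; NaN when either vector has no spread."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 2:
        return float("nan")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


def maape(observed, predicted) -> float:
    """Mean arctan absolute percentage error, in radians.

    Each term is arctan(|(y - yhat)/y|); a zero observation with a nonzero
    prediction contributes pi/2 (the arctan limit of division by zero), and
    an exact zero-zero pair contributes 0.  Always in [0, pi/2].
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    diff = np.abs(observed - predicted)
    terms = np.where(
        observed != 0,
        np.arctan(np.abs(np.divide(diff, observed,
                                   out=np.zeros_like(diff),
                                   where=observed != 0))),
        np.where(diff == 0, 0.0, np.pi / 2),
    )
    return float(terms.mean())


def _metrics_for(pheno, part, pred_matrix, model_name, part_idx, by_env):
    """Per-(trait[,env]) APC and MAAPE on one partition's test cells."""
    rows = []
    test_rows = np.array(sorted(pheno.cell_index(l, e) for l, e in part.test_cells))
    env_idx, _ = pheno.cell_line_env_index()
    for l, trait in enumerate(pheno.trait_names):
        obs_ok = pheno.mask[test_rows, l]
        r = test_rows[obs_ok]
        groups = [(None, r)]
        if by_env:
            groups += [(env, r[env_idx[r] == i])
                       for i, env in enumerate(pheno.env_ids)]
        for env, rr in groups:
            if rr.size == 0:
                continue
            y, yhat = pheno.values[rr, l], pred_matrix[rr, l]
            apc = pearson(y, yhat) if rr.size >= 2 else float("nan")
            if np.isnan(apc) and rr.size >= 2:
                warnings.warn(
                    f"APC undefined for {model_name}/{trait}"
                    f" (partition {part_idx}): zero spread")
            rows.append(dict(partition=part_idx, model=model_name, trait=trait,
                             env=env, apc=apc, maape=maape(y, yhat),
                             n_test=int(rr.size)))
    return rows


def run_cv(pheno: PhenotypeTable, grm: GenomicRelationship,
           models=("UT", "BMORS"), cfg: CVConfig | None = None,
           iterations: int = 10000, burnin: int = 5000, thin: int = 5,
           seed: int = 0, by_env: bool = False,
           predictor_override=None):
    """Cross-validate the requested models with shared partitions.

    Returns (metrics report DataFrame, per-cell predictions DataFrame).
    The UT baseline is one GBLUP per trait; BMORS stacks those same
    stage-1 fits (identical training mask and chains) with its ridge
    meta-models.  ``predictor_override`` — mapping model name to a callable
    ``(pheno, training_mask) -> N×L prediction matrix`` — replaces a
    model's fitting path and exists for oracle tests.
    """
    if cfg is None:
        cfg = CVConfig()
    unknown = set(models) - {"UT", "BMORS"}
    if predictor_override:
        unknown -= set(predictor_override)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    if not models:
        raise ValueError("no models requested")
    partitions = make_partitions(pheno, cfg)
    seeds = np.random.SeedSequence([seed, 7]).generate_state(
        cfg.n_partitions) % (2**31)
    metric_rows, pred_rows = [], []
    env_idx, line_idx = pheno.cell_line_env_index()
    for p_idx, part in enumerate(partitions):
        tmask = cells_to_training_mask(pheno, part.test_cells)
        preds = {}
        ut_fits = None
        if predictor_override:
            for name, fn in predictor_override.items():
                if name in models:
                    preds[name] = fn(pheno, tmask)
        if "UT" in models and "UT" not in preds:
            ut_fits = [
                GBLUPGxE(pheno, grm, trait=t, training_mask=tmask).fit(
                    iterations=iterations, burnin=burnin, thin=thin,
                    seed=int(seeds[p_idx]))
                for t in pheno.trait_names]
            preds["UT"] = np.column_stack([f.predict() for f in ut_fits])
        if "BMORS" in models and "BMORS" not in preds:
            res = BMORS(pheno, grm, training_mask=tmask).fit(
                iterations=iterations, burnin=burnin, thin=thin,
                seed=int(seeds[p_idx]), stage1_fits=ut_fits)
            preds["BMORS"] = res.predict()
        for name in models:
            metric_rows += _metrics_for(pheno, part, preds[name], name,
                                        p_idx, by_env)
            test_rows = sorted(pheno.cell_index(l, e)
                               for l, e in part.test_cells)
            for r in test_rows:
                for l, trait in enumerate(pheno.trait_names):
                    if not pheno.mask[r, l]:
                        continue
                    pred_rows.append(dict(
                        partition=p_idx, model=name, trait=trait,
                        env=pheno.env_ids[env_idx[r]],
                        line=pheno.line_ids[line_idx[r]],
                        observed=pheno.values[r, l],
                        predicted=preds[name][r, l]))
    per_part = pd.DataFrame(metric_rows)
    report = _aggregate(per_part)
    return report, pd.DataFrame(pred_rows)


def _aggregate(per_part: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of APC / MAAPE across partitions."""
    def agg(group):
        apc = group["apc"].dropna()
        return pd.Series({
            "APC": apc.mean() if len(apc) else float("nan"),
            "APC_SD": apc.std(ddof=1) if len(apc) > 1 else float("nan"),
            "MAAPE": group["maape"].mean(),
            "MAAPE_SD": group["maape"].std(ddof=1)
            if len(group) > 1 else float("nan"),
        })

    keys = ["model", "trait"]
    out = []
    for env_group, sub in per_part.groupby(per_part["env"].isna()):
        gkeys = keys if env_group else keys + ["env"]
        g = sub.groupby(gkeys, sort=False).apply(agg, include_groups=False)
        out.append(g.reset_index())
    report = pd.concat(out, ignore_index=True)
    report = report.rename(columns={"model": "Model", "trait": "Trait",
                                    "env": "Env"})
    cols = ["Model", "Trait"] + (["Env"] if "Env" in report else []) + \
        ["APC", "APC_SD", "MAAPE", "MAAPE_SD"]
    return report[cols]
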