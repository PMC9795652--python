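"""Host–microbiome association statistics and clinical derivations.

Quantile (median) age-adjusted regression of host variables on ordination
axes, with coefficients rescaled to the axis range (RC range) and to one
axis standard deviation (RC sd); Fisher–Freeman–Halton exact tests for
2 × k contingency tables; Cramér's V effect size; HOMA-IR / Matsuda
clinical indices; and the YFAS-based behavioral stratification of the
obese group.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from math import lgamma

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .core import SampleMetadata, ValidationError
from .stats import bh_adjust

log = logging.getLogger("microtype")

FISHER_ENUMERATION_BUDGET = 10_000_000


def quantile_assoc(
    metadata: pd.DataFrame,
    axes: pd.DataFrame,
    variables: list[str] | None = None,
    age_col: str = "age",
    n_axes: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median regression of each variable on each ordination axis, age-adjusted.

    Model: variable ~ axis + age at the 0.5 quantile, complete cases per
    variable.  Reports the raw axis coefficient beta, RC_range = beta *
    (max - min) of the axis, RC_sd = beta * sd of the axis, the axis
    p-value, and BH adjustment across the whole variable × axis grid.
    Degenerate (zero-variance) axes are skipped with a warning.
    """
    if variables is None:
        variables = [c for c in metadata.columns
                     if c != age_col and pd.api.types.is_numeric_dtype(metadata[c])]
    shared = metadata.index.intersection(axes.index)
    md = metadata.loc[shared]
    ax = axes.loc[shared]
    axis_cols = list(ax.columns[:n_axes])
    rows = []
    for var in variables:
        for axis in axis_cols:
            sub = pd.DataFrame(
                {"y": md[var], "axis": ax[axis], "age": md[age_col]}
            ).dropna()
            if len(sub) < 10:
                continue
            x = sub["axis"].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                log.warning("quantile_assoc: axis %s degenerate, skipped", axis)
                continue
            exog = sm.add_constant(sub[["axis", "age"]].to_numpy(dtype=float))
            y = sub["y"].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                rows.append({"variable": var, "axis": axis, "n": len(sub), "beta": 0.0,
                             "rc_range": 0.0, "rc_sd": 0.0, "p": 1.0})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", IterationLimitWarning)
                fit = sm.QuantReg(y, exog).fit(q=0.5)
            beta = float(fit.params[1])
            p = float(fit.pvalues[1])
            rows.append(
                {"variable": var, "axis": axis, "n": len(sub), "beta": beta,
                 "rc_range": beta * float(np.ptp(x)),
                 "rc_sd": beta * float(np.std(x, ddof=1)),
                 "p": p}
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] <= alpha
    return out


def _log_table_prob(table: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    """log P(table | margins) under the hypergeometric model."""
    return (
        sum(lgamma(x + 1) for x in lr)
        + sum(lgamma(x + 1) for x in lc)
        - ln
        - sum(lgamma(x + 1) for x in table.ravel())
    )


def fisher_2xk(table, n_mc: int = 100_000, seed: int = 0) -> dict:
    """Fisher–Freeman–Halton exact test for a 2 × k table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one.  Above
    an enumeration budget it falls back to seeded Monte Carlo sampling from
    the margin-conditional null, reporting the standard error.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValidationError("fisher_2xk expects a 2 x k table, k >= 2")
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if (row == 0).any() or (col == 0).any() or n == 0:
        return {"p": 1.0, "method": "degenerate", "se": 0.0}

    lr, lc, ln = row, col, lgamma(n + 1)
    log_p_obs = _log_table_prob(t, lr, lc, ln)
    import math

    n_candidates = math.prod(
        int(min(row[0], c) - max(0, row[0] - (n - c)) + 1) for c in col
    )

    if n_candidates <= FISHER_ENUMERATION_BUDGET:
        total = 0.0
        ranges = [range(max(0, row[0] - (n - c)), min(row[0], c) + 1) for c in col[:-1]]
        for cells in itertools.product(*ranges):
            last = row[0] - sum(cells)
            if last < 0 or last > col[-1]:
                continue
            cand = np.array([list(cells) + [last],
                             list(col[:-1] - np.array(cells)) + [col[-1] - last]])
            lp = _log_table_prob(cand, lr, lc, ln)
            if lp <= log_p_obs + 1e-10:
                total += np.exp(lp)
        return {"p": float(min(total, 1.0)), "method": "enumeration", "se": 0.0}

    # Monte Carlo: sample tables with fixed margins via random bipartition
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(col)), col)
    hits = 0
    for _ in range(n_mc):
        pick = rng.permutation(pool)[: row[0]]
        top = np.bincount(pick, minlength=len(col))
        cand = np.array([top, col - top])
        if _log_table_prob(cand, lr, lc, ln) <= log_p_obs + 1e-10:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return {"p": float(p), "method": "monte_carlo", "se": se}


def cramers_v(table) -> float:
    """Cramér's V = sqrt(chi2 / (n * (min(r, c) - 1))), uncorrected chi-square."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or t.sum() <= 0:
        raise ValidationError("counts must be non-negative with a positive total")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("zero margin: Cramér's V undefined")
    n = t.sum()
    expected = np.outer(row, col) / n
    chi2 = ((t - expected) ** 2 / expected).sum()
    r, c = t.shape
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def clinical_indices(metadata: SampleMetadata) -> pd.DataFrame:
    """HOMA-IR, insulin-resistance flag, and (when OGTT means exist) Matsuda.

    HOMA-IR = fasting glucose [mg/dl] x fasting insulin [uU/ml] / 405;
    insulin resistant iff HOMA-IR > 2.5 (strict).  Matsuda = 10000 /
    sqrt(G0 * I0 * Gmean * Imean).  Non-positive inputs yield NaN.
    """
    df = metadata.data
    g = pd.to_numeric(df.get("fasting_glucose"), errors="coerce")
    i = pd.to_numeric(df.get("fasting_insulin"), errors="coerce")
    valid = (g > 0) & (i > 0)
    homa = pd.Series(np.where(valid, g * i / 405.0, np.nan), index=df.index, name="homa_ir")
    out = pd.DataFrame({"homa_ir": homa})
    ir = pd.Series(homa > 2.5, index=homa.index, dtype="boolean")
    ir[homa.isna()] = pd.NA
    out["insulin_resistant"] = ir
    if {"glucose_mean", "insulin_mean"} <= set(df.columns):
        gm = pd.to_numeric(df["glucose_mean"], errors="coerce")
        im = pd.to_numeric(df["insulin_mean"], errors="coerce")
        prod = g * i * gm * im
        out["matsuda"] = np.where(prod > 0, 10000.0 / np.sqrt(prod), np.nan)
    return out


def yfas_stratify(metadata: SampleMetadata) -> pd.Series:
    """Behavioral strata for the obese group from YFAS scores.

    OB with >= 3 symptoms and a food-addiction diagnosis -> O_DHA; >= 3
    symptoms without diagnosis -> O_HA; <= 2 symptoms -> O_LA.  NW samples
    (and samples missing scores) are left unassigned.
    """
    df = metadata.data
    needed = {"weight_group", "yfas_symptoms", "yfas_diagnosis"}
    if not needed <= set(df.columns):
        raise ValidationError(f"metadata lacks columns: {sorted(needed - set(df.columns))}")
    sym = pd.to_numeric(df["yfas_symptoms"], errors="coerce")
    diag = df["yfas_diagnosis"].astype("boolean")
    bad = (diag.fillna(False)) & (sym < 3)
    if bad.any():
        raise ValidationError(
            f"diagnosis with < 3 symptoms violates the instrument: {df.index[bad].tolist()}"
        )
    out = pd.Series(pd.NA, index=df.index, dtype="object", name="behavior_group")
    ob = df["weight_group"] == "OB"
    out[ob & (sym >= 3) & diag.fillna(False)] = "O_DHA"
    out[ob & (sym >= 3) & ~diag.fillna(False)] = "O_HA"
    out[ob & (sym <= 2)] = "O_LA"
    return out
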