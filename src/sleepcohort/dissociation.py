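"""Sleep-onset vs sleep-maintenance dissociation against behavior.

Correlates EEG-derived SOL and WASO (from two independent staging
pipelines, then their per-child average) with behavior questionnaire
scores across all children, and tests whether, for each scale, the SOL
correlation is stronger than the WASO correlation with Steiger's (1980)
Z test for dependent correlations sharing a variable:

    Z = (z1 − z2) · sqrt((n − 3) / (2·(1 − s)))

where z1, z2 are Fisher transforms of r(SOL, b) and r(WASO, b), and s is
the asymptotic correlation between them computed from r(SOL, WASO) with
the pooled mean correlation r̄ = (r1 + r2)/2:

    s = [ r12·(1 − 2·r̄²) − ½·r̄²·(1 − 2·r̄² − r12²) ] / (1 − r̄²)²

Cell p-values are deliberately uncorrected (sensitivity over strict
control); the Steiger comparison is two-sided.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def pearson_cell(sleep_vals, behavior_vals) -> dict:
    """One correlation cell: Pearson r, n, uncorrected p (NaN-safe pairwise)."""
    s = np.asarray(sleep_vals, dtype=float)
    b = np.asarray(behavior_vals, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(b))
    s, b = s[keep], b[keep]
    if len(s) < 3 or np.ptp(s) == 0 or np.ptp(b) == 0:
        return {"r": np.nan, "n": int(len(s)), "p": np.nan, "computable": False}
    r, p = stats.pearsonr(s, b)
    return {"r": float(r), "n": int(len(s)), "p": float(p), "computable": True}


def behavior_sleep_corr(sleep: pd.DataFrame, behavior: pd.DataFrame,
                        sleep_cols: Sequence[str],
                        scales: Sequence[str]) -> pd.DataFrame:
    """Correlation matrix: (sleep measure × estimator) rows vs behavior scales.

    ``sleep`` holds one row per child with columns ``sleep_cols`` (e.g.
    sol_eeg_algo, waso_mean); ``behavior`` one row per child with the scale
    columns. Alignment is on child_id; missing pairs are dropped per cell
    (pairwise-complete) and the realized n is recorded.
    """
    merged = sleep.merge(behavior, on="child_id", how="inner",
                         suffixes=("", "_beh"))
    rows = []
    for sc in sleep_cols:
        for scale in scales:
            cell = pearson_cell(merged[sc], merged[scale])
            rows.append({"sleep_measure": sc, "scale": scale, **cell})
    return pd.DataFrame(rows)


def average_algorithms(per_child: pd.DataFrame, col_a: str, col_b: str,
                       out: str) -> pd.DataFrame:
    """Per-child mean of two estimators' values; children missing either
    estimate are excluded (count reported in the attrs)."""
    complete = per_child.dropna(subset=[col_a, col_b]).copy()
    complete[out] = (complete[col_a] + complete[col_b]) / 2.0
    complete.attrs["n_excluded_incomplete"] = len(per_child) - len(complete)
    return complete


def steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's Z for H0: ρ(x1, b) = ρ(x2, b) with shared variable b.

    ``r1`` = r(x1, b), ``r2`` = r(x2, b), ``r12`` = r(x1, x2). Returns
    (Z, two-sided p). Antisymmetric in (r1, r2).
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
    if n < 4:
        raise ValueError("n must be >= 4")
    # positive-definiteness of the 3x3 correlation matrix
    det = 1 + 2 * r1 * r2 * r12 - r1 ** 2 - r2 ** 2 - r12 ** 2
    if det <= 0:
        raise ValueError("inconsistent correlation triple (not positive definite)")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    num = r12 * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r12 ** 2)
    s = num / (1 - rbar ** 2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def run_dissociation(per_child_sleep: pd.DataFrame, behavior: pd.DataFrame,
                     scales: Sequence[str],
                     algo_a: str = "eeg_algo", algo_b: str = "eeg_external",
                     alpha: float = 0.05) -> dict:
    """Full report: per-algorithm matrices, averaged matrix, Steiger tests.

    ``per_child_sleep`` needs one row per child with columns
    ``sol_<algo>`` and ``waso_<algo>`` for both algorithms. Deterministic:
    no randomness in this stage.
    """
    need = [f"{m}_{a}" for m in ("sol", "waso") for a in (algo_a, algo_b)]
    missing = [c for c in need if c not in per_child_sleep.columns]
    if missing:
        raise ValueError(f"per-child sleep table lacks columns {missing}")

    per_algo = {}
    for a in (algo_a, algo_b):
        per_algo[a] = behavior_sleep_corr(
            per_child_sleep, behavior,
            sleep_cols=[f"sol_{a}", f"waso_{a}"], scales=scales)

    avg = per_child_sleep.copy()
    avg = average_algorithms(avg, f"sol_{algo_a}", f"sol_{algo_b}", "sol_mean")
    avg = average_algorithms(avg, f"waso_{algo_a}", f"waso_{algo_b}", "waso_mean")
    mean_matrix = behavior_sleep_corr(avg, behavior,
                                      sleep_cols=["sol_mean", "waso_mean"],
                                      scales=scales)

    merged = avg.merge(behavior, on="child_id", how="inner",
                       suffixes=("", "_beh"))
    steiger_rows = []
    for scale in scales:
        sub = merged.dropna(subset=["sol_mean", "waso_mean", scale])
        n = len(sub)
        if n < 4:
            steiger_rows.append({"scale": scale, "z": np.nan, "p": np.nan,
                                 "n": n, "computable": False})
            continue
        r_sol = stats.pearsonr(sub["sol_mean"], sub[scale])[0]
        r_waso = stats.pearsonr(sub["waso_mean"], sub[scale])[0]
        r_sw = stats.pearsonr(sub["sol_mean"], sub["waso_mean"])[0]
        z, p = steiger_z(r_sol, r_waso, r_sw, n)
        steiger_rows.append({"scale": scale, "r_sol": float(r_sol),
                             "r_waso": float(r_waso), "r_sol_waso": float(r_sw),
                             "z": z, "p": p, "n": n,
                             "significant": p < alpha, "computable": True})
    mean_matrix["significant"] = mean_matrix["p"] < alpha
    for a in per_algo:
        per_algo[a]["significant"] = per_algo[a]["p"] < alpha
    return {"per_algorithm": per_algo, "mean_matrix": mean_matrix,
            "steiger": pd.DataFrame(steiger_rows)}
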