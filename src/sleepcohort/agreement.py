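"""Agreement between paired sleep-measure sources.

Lin's concordance correlation coefficient (CCC) measures absolute
agreement — error is distance from the identity line, not from a fitted
line — so it penalizes both scatter and systematic bias:

    CCC = 2·cov(x, y) / (var(x) + var(y) + (mean x − mean y)²)

with population (n-denominator) moments, per Lin's original estimator.
Significance comes from a permutation null: one vector's night labels are
shuffled (5,000 iterations by default) and the observed CCC must exceed
the top 0.1th percentile of the null — a one-sided test at p = 0.001,
chosen conservatively in place of an explicit multiplicity correction.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .dtypes import MISSING, SLEEP, WAKE, AgreementResult, EpochSeries

MEASURES = ("so_noon_min", "fa_noon_min", "waso_min", "tst_min")


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before agreement")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("CCC undefined: both vectors are constant")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (n-denominator moments)."""
    x, y = _check_pair(x, y)
    vx, vy = x.var(), y.var()
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def pearson(x, y) -> float:
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def ccc_permutation_null(x, y, n_iter: int = 5000,
                         rng: Optional[np.random.Generator] = None
                         ) -> np.ndarray:
    """Null CCC distribution from shuffling y's night labels.

    Vectorized: only cov(x, y_perm) changes under permutation, so the null
    values are affine in the permuted cross-products.
    """
    x, y = _check_pair(x, y)
    if rng is None:
        rng = np.random.default_rng()
    n = len(x)
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    xc = x - x.mean()
    yc = y - y.mean()
    idx = np.argsort(rng.random((n_iter, n)), axis=1)  # uniform permutations
    cross = yc[idx] @ xc / n
    return 2.0 * cross / denom


def ccc_permutation_p(x, y, n_iter: int = 5000,
                      seed: int | np.random.Generator | None = 0
                      ) -> tuple[float, float, np.ndarray, bool]:
    """(observed CCC, permutation p, null distribution, significant flag).

    p uses the add-one estimator (1 + #{null >= obs}) / (1 + n_iter), which
    cannot return 0; ``significant`` means the observed CCC exceeds the
    null's 99.9th percentile (the top 0.1th-percentile rule).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = ccc(x, y)
    null = ccc_permutation_null(x, y, n_iter=n_iter, rng=rng)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_iter)
    significant = bool(obs > np.percentile(null, 99.9))
    return obs, float(p), null, significant


def pair_agreement(x, y, measure: str, source_a: str, source_b: str,
                   n_iter: int = 5000, seed=0) -> AgreementResult:
    obs, p, _null, sig = ccc_permutation_p(x, y, n_iter=n_iter, seed=seed)
    return AgreementResult(measure=measure, source_a=source_a,
                           source_b=source_b, ccc=obs, pearson_r=pearson(x, y),
                           n=len(np.asarray(x)), p_value=p,
                           n_iterations=n_iter, significant=sig)


def agreement_matrix(table: pd.DataFrame, level: str = "per_night",
                     sources: Optional[list[str]] = None,
                     measures: Iterable[str] = MEASURES,
                     cshq: Optional[pd.DataFrame] = None,
                     n_iter: int = 5000, seed: int = 0,
                     min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise CCC matrix per measure across sources.

    ``level='per_night'`` aligns sources on (child, night) rows;
    ``level='per_child'`` first averages each measure across a child's
    nights per source, and admits the questionnaire (``cshq``) as an extra
    source since it reports one typical value per child. Cells with fewer
    than ``min_pairs`` aligned pairs are marked not-computable (NaN).
    """
    if level not in ("per_night", "per_child"):
        raise ValueError("level must be per_night or per_child")
    if sources is None:
        sources = sorted(table["source"].unique())
    rows = []
    rng = np.random.default_rng(seed)
    for measure in measures:
        wide = _align(table, measure, level)
        if level == "per_child" and cshq is not None and measure in cshq.columns:
            extra = cshq.set_index("child_id")[measure].rename("cshq")
            wide = wide.join(extra, how="left")
        cols = [s for s in ([*sources, "cshq"] if level == "per_child" and
                            cshq is not None else sources) if s in wide.columns]
        for i, a in enumerate(cols):
            for b in cols[i:]:
                sub = wide[[a, b]].dropna() if a != b else wide[[a]].dropna()
                n = len(sub)
                if a == b:
                    rows.append(dict(measure=measure, source_a=a, source_b=b,
                                     ccc=1.0, pearson_r=1.0, n=n,
                                     p_value=np.nan, significant=True))
                    continue
                if n < min_pairs:
                    rows.append(dict(measure=measure, source_a=a, source_b=b,
                                     ccc=np.nan, pearson_r=np.nan, n=n,
                                     p_value=np.nan, significant=False))
                    continue
                res = pair_agreement(sub[a].values, sub[b].values, measure,
                                     a, b, n_iter=n_iter,
                                     seed=np.random.default_rng(rng.integers(2**31)))
                rows.append(dict(measure=measure, source_a=a, source_b=b,
                                 ccc=res.ccc, pearson_r=res.pearson_r, n=n,
                                 p_value=res.p_value,
                                 significant=res.significant))
    cols = ["measure", "source_a", "source_b", "ccc", "pearson_r", "n",
            "p_value", "significant"]
    out = pd.DataFrame(rows, columns=cols)
    mirror = out[out.source_a != out.source_b].rename(
        columns={"source_a": "source_b", "source_b": "source_a"})
    return (pd.concat([out, mirror], ignore_index=True)
            .sort_values(["measure", "source_a", "source_b"])
            .reset_index(drop=True))


def _align(table: pd.DataFrame, measure: str, level: str) -> pd.DataFrame:
    df = table.dropna(subset=[measure])
    if level == "per_night":
        return df.pivot_table(index=["child_id", "night_date"],
                              columns="source", values=measure,
                              aggfunc="first")
    per_child = (df.groupby(["child_id", "source"])[measure].mean()
                   .unstack("source"))
    return per_child


# ---------------------------------------------------------------------------
# Epoch-level sleep/wake concordance between two devices
# ---------------------------------------------------------------------------

def epoch_confusion(a: EpochSeries, b: EpochSeries,
                    ) -> tuple[float, Optional[float]]:
    """(sensitivity, specificity) of series b against reference a.

    Series are aligned on their overlapping wall-clock span at the coarser
    epoch size (the finer series votes by majority within each coarse
    epoch, ties to WAKE); MISSING epochs are dropped pairwise. Sensitivity
    is the fraction of reference SLEEP epochs also labeled SLEEP;
    specificity the fraction of reference WAKE epochs labeled WAKE (None
    when the reference has no wake epochs in the overlap).
    """
    step = max(a.epoch_s, b.epoch_s)
    start = max(a.recording_start, b.recording_start)
    end = min(a.epoch_time(a.n_epochs), b.epoch_time(b.n_epochs))
    if end <= start:
        raise ValueError("series do not overlap in time")
    la = _resample(a, start, end, step)
    lb = _resample(b, start, end, step)
    keep = (la != MISSING) & (lb != MISSING)
    la, lb = la[keep], lb[keep]
    if la.size == 0:
        raise ValueError("no jointly non-missing epochs in the overlap")
    ref_sleep = la == SLEEP
    ref_wake = la == WAKE
    sens = float(np.mean(lb[ref_sleep] == SLEEP)) if ref_sleep.any() else float("nan")
    spec = float(np.mean(lb[ref_wake] == WAKE)) if ref_wake.any() else None
    return sens, spec


def _resample(s: EpochSeries, start, end, step: int) -> np.ndarray:
    """Labels of s on the [start, end) grid with step seconds per epoch."""
    if s.is_multichannel:
        raise ValueError("epoch_confusion expects single-channel binary series")
    n_out = int((end - start).total_seconds() // step)
    out = np.empty(n_out, dtype=object)
    off = (start - s.recording_start).total_seconds()
    per = step // s.epoch_s  # fine epochs per coarse epoch (>= 1)
    for i in range(n_out):
        j0 = int((off + i * step) // s.epoch_s)
        chunk = s.labels[j0: j0 + per]
        n_sleep = int(np.sum(chunk == SLEEP))
        n_wake = int(np.sum(chunk == WAKE))
        if n_sleep == 0 and n_wake == 0:
            out[i] = MISSING
        elif n_sleep > n_wake:
            out[i] = SLEEP
        else:
            out[i] = WAKE  # ties conservatively to wake
    return out
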