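"""Correlation/error metrics and evaluation protocols.

Agreement between predicted scores and the radiologist MOS is summarized by
four standard IQA statistics: Pearson's linear correlation (PLCC), Spearman's
rank correlation with average ranks on ties (SRCC), Kendall's tau-b (KRCC),
and the root mean squared error on the 1-5 MOS scale (RMSE). SRCC/KRCC are
invariant to strictly monotone transforms of the predictions; PLCC to positive
affine ones. No logistic remapping is applied before PLCC by default (a flag
exists for comparison with harnesses that do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class EvalResult:
    plcc: float
    srcc: float
    krcc: float
    rmse: float
    n: int


def _logistic_remap(pred: np.ndarray, mos: np.ndarray) -> np.ndarray:
    """4-parameter logistic fit of predictions onto the MOS scale."""

    def f(x, a, b, c, d):
        return (a - b) / (1 + np.exp(-(x - c) / np.maximum(np.abs(d), 1e-6))) + b

    p0 = (mos.max(), mos.min(), pred.mean(), pred.std() + 1e-6)
    try:
        popt, _ = optimize.curve_fit(f, pred, mos, p0=p0, maxfev=5000)
        return f(pred, *popt)
    except RuntimeError:
        return pred


def compute_metrics(predicted, mos, logistic_remap: bool = False) -> EvalResult:
    """PLCC/SRCC/KRCC/RMSE for paired (predicted, MOS) vectors.

    Raises ValueError for fewer than 3 pairs or a constant input vector
    (correlations are undefined there — the error is explicit, never a
    silent zero).
    """
    pred = np.asarray(predicted, dtype=np.float64).ravel()
    y = np.asarray(mos, dtype=np.float64).ravel()
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape[0]} vs {y.shape[0]}")
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    pred_lin = _logistic_remap(pred, y) if logistic_remap else pred
    plcc = float(stats.pearsonr(pred_lin, y).statistic)
    srcc = float(stats.spearmanr(pred, y).statistic)
    krcc = float(stats.kendalltau(pred, y).statistic)  # tau-b (tie-corrected)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return EvalResult(plcc=plcc, srcc=srcc, krcc=krcc, rmse=rmse,
                      n=int(pred.shape[0]))


def evaluate_model(state, test_groups, repeats: int = 1, seed: int = 0,
                   logistic_remap: bool = False):
    """Score every test image and compute metrics against MOS.

    With ``repeats > 1`` the metrics are additionally averaged over that many
    resampled 80% subsets of the test images (repeated-evaluation averaging).
    Returns (EvalResult, per-image DataFrame).
    """
    if not test_groups:
        raise ValueError("test set is empty")
    rows = []
    pixels, mos = [], []
    for g in test_groups:
        for v in g.variants:
            pixels.append(v.pixels)
            mos.append(v.mos)
            rows.append({"group_id": g.group_id, "variant_id": v.variant_id,
                         "mos": v.mos})
    mos = np.asarray(mos, dtype=np.float64)
    preds = state.predict_mos(np.stack(pixels))
    table = pd.DataFrame(rows)
    table["predicted"] = preds
    if repeats <= 1:
        return compute_metrics(preds, mos, logistic_remap), table
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xE7A1)))
    n = preds.shape[0]
    k = max(int(round(0.8 * n)), 3)
    vals = []
    for _ in range(repeats):
        idx = rng.choice(n, size=k, replace=False)
        try:
            r = compute_metrics(preds[idx], mos[idx], logistic_remap)
        except ValueError:
            continue
        vals.append((r.plcc, r.srcc, r.krcc, r.rmse))
    if not vals:
        return compute_metrics(preds, mos, logistic_remap), table
    m = np.mean(np.asarray(vals), axis=0)
    return EvalResult(plcc=float(m[0]), srcc=float(m[1]), krcc=float(m[2]),
                      rmse=float(m[3]), n=n), table


def split_sweep(groups, fractions, cfg) -> pd.DataFrame:
    """Train one model per training fraction (grouped split) and evaluate on
    the complement; returns a table of (fraction, PLCC, SRCC, KRCC, RMSE, n).

    Replicates the train-fraction sweep design: as the training share grows
    from 20% to 80%, held-out performance should rise.
    """
    from .training import fit  # local import to avoid a module cycle

    groups = list(groups)
    n = len(groups)
    rows = []
    for frac in fractions:
        frac = float(frac)
        if not (0.0 < frac < 1.0):
            raise ValueError(f"training fraction must lie in (0, 1), got {frac}")
        n_train = int(round(frac * n))
        if n_train < 1 or n_train >= n:
            raise ValueError(
                f"fraction {frac} leaves an empty train or test side (n={n})")
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, 0x5E1, int(frac * 1000))))
        perm = rng.permutation(n)
        train = [groups[i] for i in perm[:n_train]]
        test = [groups[i] for i in perm[n_train:]]
        state, _ = fit(train, test, cfg)
        res, _ = evaluate_model(state, test, repeats=1, seed=cfg.seed)
        rows.append({"fraction": frac, "plcc": res.plcc, "srcc": res.srcc,
                     "krcc": res.krcc, "rmse": res.rmse, "n": res.n})
    return pd.DataFrame(rows)
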