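"""Quantitative-PCR analysis: standard-curve primer efficiency, the
comparative ddCT (2^-ddCT) relative-expression method, and the
summary-statistic Student's t-test used for two-group comparisons.

CT tables are tidy DataFrames with columns (animal, group, gene, pool, ct);
one reference gene normalizes the targets within each pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class QpcrError(ValueError):
    pass


REQUIRED_COLUMNS = ("animal", "group", "gene", "pool", "ct")


def primer_efficiency(slope: float, cap: float = 100.0) -> int:
    """Amplification efficiency E = 10^(-1/m) - 1 from a standard-curve
    slope m (CT cycles per log10 dilution), as an integer percentage.

    A perfect doubling per cycle has m = -1/log10(2) = -3.3219 and E = 100%.
    Steeper-than-perfect slopes arise from fitting noise, so the reported
    percentage is capped at 100, matching how standard-curve tables round."""
    if slope >= 0:
        raise QpcrError("standard-curve slope must be negative")
    e = 10.0 ** (-1.0 / slope) - 1.0
    return int(round(min(100.0 * e, cap)))


def validate_ct_table(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"CT table lacks columns: {missing}")
    if not np.all(np.isfinite(df["ct"])) or (df["ct"] <= 0).any():
        raise QpcrError("CT values must be positive and finite")


def ddct_fold_change(df: pd.DataFrame, target_gene: str, reference_gene: str,
                     calibrator_group: str) -> pd.DataFrame:
    """Per-animal relative expression of ``target_gene`` by the comparative
    ddCT method.

    dCT = target CT - reference CT within each pool; ddCT subtracts the mean
    dCT of the calibrator group; relative quantity = 2^-ddCT.  Per-animal
    values average that animal's pools, the unit of analysis for group
    statistics.  The calibrator group's mean 2^-ddCT of per-pool values is 1
    by construction."""
    validate_ct_table(df)
    genes = set(df["gene"])
    if target_gene not in genes or reference_gene not in genes:
        raise QpcrError(f"genes {target_gene!r}/{reference_gene!r} not in table")
    if calibrator_group not in set(df["group"]):
        raise QpcrError(f"calibrator group {calibrator_group!r} not in table")
    if df["group"].nunique() < 2:
        raise QpcrError("need at least two groups")

    key = ["animal", "group", "pool"]
    tgt = df[df["gene"] == target_gene].set_index(key)["ct"]
    ref = df[df["gene"] == reference_gene].set_index(key)["ct"]
    common = tgt.index.intersection(ref.index)
    if len(common) < len(tgt):
        raise QpcrError("reference-gene CT missing for some pools")
    dct = (tgt.loc[common] - ref.loc[common]).rename("dct").reset_index()
    calib = dct.loc[dct["group"] == calibrator_group, "dct"].mean()
    dct["ddct"] = dct["dct"] - calib
    dct["rq"] = 2.0 ** (-dct["ddct"])
    per_animal = (dct.groupby(["animal", "group"], as_index=False)
                  .agg(fold_change=("rq", "mean"), n_pools=("rq", "size")))
    per_animal.insert(0, "gene", target_gene)
    return per_animal


def group_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of per-animal fold changes by group."""
    g = per_animal.groupby("group")["fold_change"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def t_from_summary(mean1: float, sem1: float, n1: int,
                   mean2: float, sem2: float, n2: int,
                   welch: bool = False) -> TTestResult:
    """Unpaired two-tailed Student's t-test from group summary statistics.

    Group SDs are recovered as SD_i = SEM_i * sqrt(n_i).  The default is the
    pooled-variance test with df = n1 + n2 - 2; ``welch=True`` uses the
    unequal-variance form with Welch-Satterthwaite df."""
    if n1 < 2 or n2 < 2:
        raise QpcrError("need n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise QpcrError("SEMs must be positive")
    v1, v2 = (sem1 ** 2) * n1, (sem2 ** 2) * n2   # variances
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))
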