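"""Per-seed and per-genotype statistics, classification and shell volumes.

Measurements are aggregated as means and sample standard deviations (n-1
denominator), per seed over its measurement sites and per genotype pooled
over all site-level measurements.  Genotype differences are tested with the
pooled-variance (Student) two-sample t-test; seeds are classified thin/thick
against a 53 um mean-thickness threshold; an ellipsoidal-shell model converts
mean thickness to pericarp volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Mean-thickness classification threshold (um) separating thin- from
#: thick-pericarp phenotypes.
CLASSIFICATION_THRESHOLD_UM = 53.0


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise StatsError("p must be in [0, 1]")


def classify(mean_um: float, threshold_um: float = CLASSIFICATION_THRESHOLD_UM) -> str:
    """Label a seed 'thin' below the threshold, 'thick' at or above it."""
    if not mean_um > 0:
        raise StatsError("mean thickness must be > 0")
    return "thick" if mean_um >= threshold_um else "thin"


def summarize(
    measurements: pd.DataFrame,
    threshold_um: float = CLASSIFICATION_THRESHOLD_UM,
    known_genotypes: tuple[str, ...] = ("thick", "thin"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-seed and per-genotype summaries of a measurement table.

    ``measurements`` needs columns seed_id, genotype, thickness_um.  Seed
    summaries average over sites; genotype summaries pool all site-level
    measurements of the genotype's seeds (sample SD, n-1).  Row order of the
    input is irrelevant.
    """
    required = {"seed_id", "genotype", "thickness_um"}
    if not required <= set(measurements.columns):
        raise StatsError(f"measurement table needs columns {sorted(required)}")
    unknown = set(measurements["genotype"]) - set(known_genotypes)
    if unknown:
        raise StatsError(f"unknown genotype labels: {sorted(unknown)}")
    df = measurements.sort_values(["genotype", "seed_id"], kind="stable")
    seed = (
        df.groupby(["genotype", "seed_id"], sort=True)["thickness_um"]
        .agg(n="count", mean_um="mean", sd_um=lambda v: v.std(ddof=1))
        .reset_index()
    )
    seed["sd_um"] = seed["sd_um"].fillna(0.0)
    seed["label"] = [classify(m, threshold_um) for m in seed["mean_um"]]
    geno = (
        df.groupby("genotype", sort=True)["thickness_um"]
        .agg(n="count", mean_um="mean", sd_um=lambda v: v.std(ddof=1))
        .reset_index()
    )
    geno["sd_um"] = geno["sd_um"].fillna(0.0)
    geno["n_seeds"] = seed.groupby("genotype")["seed_id"].count().values
    geno["label"] = [classify(m, threshold_um) for m in geno["mean_um"]]
    return seed, geno


def student_t(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test; pooled-variance (Student) by default, Welch as an
    option.  Degenerate zero-variance inputs follow documented conventions:
    equal means give t = 0, p = 1; unequal means give p = 0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        warnings.warn("zero pooled variance with unequal means: p = 0", stacklevel=2)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, df, 0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if not equal_var:
        df = int(np.floor(res.df))
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need paired vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("constant input has undefined correlation")
    return float(sps.pearsonr(x, y).statistic)


def shell_volume(a_mm: float, b_mm: float, c_mm: float, t_mm: float) -> float:
    """Pericarp volume of an ellipsoidal shell (mm^3).

    V = (4 pi / 3) [abc - (a - t)(b - t)(c - t)]: the volume between the
    outer ellipsoid and an inner ellipsoid whose semi-axes are uniformly
    shorter by the shell thickness t.
    """
    if min(a_mm, b_mm, c_mm) <= 0:
        raise StatsError("semi-axes must be > 0")
    if t_mm < 0 or t_mm >= min(a_mm, b_mm, c_mm):
        raise StatsError("need 0 <= t < min(a, b, c)")
    return float(
        4.0
        * np.pi
        / 3.0
        * (a_mm * b_mm * c_mm - (a_mm - t_mm) * (b_mm - t_mm) * (c_mm - t_mm))
    )


def build_report(
    measurements: pd.DataFrame,
    threshold_um: float = CLASSIFICATION_THRESHOLD_UM,
    semi_axes_mm: tuple[float, float, float] | None = None,
) -> dict:
    """Genotype-level report: means, SDs, pooled t-test, classification table,
    and (optionally) shell-volume conversions of the genotype means."""
    seed, geno = summarize(measurements, threshold_um)
    groups = {
        g: measurements.loc[measurements["genotype"] == g, "thickness_um"].to_numpy()
        for g in geno["genotype"]
    }
    report: dict = {
        "threshold_um": threshold_um,
        "genotypes": {
            row["genotype"]: {
                "n": int(row["n"]),
                "n_seeds": int(row["n_seeds"]),
                "mean_um": float(row["mean_um"]),
                "sd_um": float(row["sd_um"]),
            }
            for _, row in geno.iterrows()
        },
        "seeds": seed.to_dict(orient="records"),
    }
    if len(groups) == 2:
        (ga, va), (gb, vb) = sorted(groups.items())
        tt = student_t(va, vb)
        report["t_test"] = {"groups": [ga, gb], "t": tt.t, "df": tt.df, "p": tt.p}
        correct = sum(
            1
            for _, row in seed.iterrows()
            if row["label"] == row["genotype"]
        )
        report["classification"] = {
            "n_seeds": int(len(seed)),
            "n_correct": int(correct),
            "accuracy_pct": 100.0 * correct / len(seed),
        }
    if semi_axes_mm is not None:
        report["shell_volume_mm3"] = {
            g: shell_volume(*semi_axes_mm, report["genotypes"][g]["mean_um"] * 1e-3)
            for g in report["genotypes"]
        }
    return report


def write_report(path, report: dict) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2)
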