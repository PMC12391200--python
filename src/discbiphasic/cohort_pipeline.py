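"""Regional statistics over per-specimen results and pipeline orchestration.

The regional analysis uses fixed-effects one-way ANOVA, pairwise Welch
(unequal-variance) t tests with Bonferroni-Holm adjustment, and pooled
Pearson correlations against porosity.  A donor random-intercept model
is deliberately not fit; donor effects in the synthetic generator are
small, and the fixed-effects approximation is stated in the report
header.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biphasic_core import LoadProtocol
from .composition import read_weights_csv
from .creep_fit import fit_specimen, read_specimen_dir
from .errors import DataQualityError, DiscBiphasicError, DomainError

__all__ = ["summarize_regions", "oneway_anova", "pairwise_holm",
           "pearson_corr", "holm_adjust", "welch_t", "run_pipeline",
           "CohortTable"]

REGIONS = ("NP", "AF", "CEP")

# outcomes analysed regionally: column -> pretty label
OUTCOMES = {
    "swelling_pressure_kPa": "swelling pressure (kPa)",
    "H_A_MPa": "aggregate modulus (MPa)",
    "k_1e-16_m4_Ns": "permeability (1e-16 m^4/N/s)",
}


@dataclass
class CohortTable:
    """One row per specimen; wraps a DataFrame with schema checks."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"specimen_id", "region"}
        missing = required - set(self.df.columns)
        if missing:
            raise DomainError(f"cohort table missing columns {sorted(missing)}")
        if self.df["specimen_id"].duplicated().any():
            raise DomainError("duplicated specimen_id in cohort table")
        bad = set(self.df["region"]) - set(REGIONS)
        if bad:
            raise DomainError(f"unknown regions {sorted(bad)}")


def summarize_regions(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Region-wise mean, SD and t-based 95% CI for ``outcome``."""
    if outcome not in table.columns:
        raise DomainError(f"outcome {outcome!r} not in table")
    rows = []
    for region, grp in table.groupby("region"):
        x = grp[outcome].dropna().to_numpy(dtype=float)
        n = len(x)
        if n < 2:
            raise DomainError(f"region {region} has fewer than 2 specimens")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        rows.append({"region": region, "n": n, "mean": mean, "sd": sd,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows).set_index("region")


def oneway_anova(table: pd.DataFrame, outcome: str) -> tuple[float, tuple[int, int], float]:
    """Classical fixed-effects one-way ANOVA: (F, (df1, df2), p)."""
    groups = [g[outcome].dropna().to_numpy(dtype=float)
              for _, g in table.groupby("region")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("need >= 2 groups with >= 2 observations each")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_x) - len(groups)
    if ss_within == 0 and ss_between == 0:
        raise DomainError("degenerate data: zero variance everywhere")
    if ss_within == 0:
        return math.inf, (df1, df2), 0.0
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise DomainError("need >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise DomainError("zero variance in both groups")
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def holm_adjust(p_raw) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment.

    Sort ascending, multiply by (m - rank + 1), enforce monotonicity of
    the adjusted values, cap at 1; returned in the input order.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pairwise_holm(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Welch t for every region pair with Holm-adjusted p-values."""
    present = [r for r in REGIONS if r in set(table["region"])]
    if len(present) < 2:
        raise DomainError("need at least two regions")
    rows = []
    for a, b in combinations(present, 2):
        x = table.loc[table["region"] == a, outcome].dropna().to_numpy(float)
        y = table.loc[table["region"] == b, outcome].dropna().to_numpy(float)
        t, df, p = welch_t(x, y)
        rows.append({"pair": f"{a}-{b}", "t": t, "df": df, "p_raw": p,
                     "mean_diff": float(x.mean() - y.mean())})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def pearson_corr(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise DomainError("need at least 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DomainError("zero variance in x or y")
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p, n


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    data_dir: Path,
    out_dir: Path,
    protocol: LoadProtocol = LoadProtocol(),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Fit every specimen, merge porosity, run regional statistics.

    Writes ``cohort.csv``, ``report.json`` and ``summary.md`` under
    ``out_dir``.  Per-specimen failures are collected in a manifest and
    do not abort the run.  Returns (cohort table, stats report).
    """
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    specimen_ids = read_specimen_dir(data_dir)
    if not specimen_ids:
        raise DomainError(f"no specimens found in {data_dir}")

    records, failures = [], []
    for sid in specimen_ids:
        try:
            fit = fit_specimen(data_dir, sid, protocol)
            records.append(fit.to_record())
        except (DataQualityError, DiscBiphasicError, OSError, KeyError,
                ValueError) as exc:
            failures.append({"specimen_id": sid, "error": f"{type(exc).__name__}: {exc}"})
    if not records:
        raise DomainError("every specimen failed to fit")
    cohort = pd.DataFrame(records)

    weights_path = data_dir / "weights.csv"
    if weights_path.exists():
        wdf = read_weights_csv(weights_path)[["specimen_id", "porosity"]]
        cohort = cohort.merge(wdf, on="specimen_id", how="left")
    else:
        cohort["porosity"] = np.nan

    table = CohortTable(cohort).df
    table.to_csv(out_dir / "cohort.csv", index=False)

    report: dict = {
        "note": ("fixed-effects one-way ANOVA + Welch pairwise tests with "
                 "Bonferroni-Holm adjustment; donor random effects are not "
                 "modeled"),
        "alpha": alpha,
        "n_specimens": int(len(table)),
        "failures": failures,
        "outcomes": {},
        "correlations": {},
    }
    for col, label in OUTCOMES.items():
        if col not in table.columns or table[col].notna().sum() < 4:
            continue
        summary = summarize_regions(table, col)
        F, (df1, df2), p = oneway_anova(table, col)
        pw = pairwise_holm(table, col)
        report["outcomes"][col] = {
            "label": label,
            "regions": summary.reset_index().to_dict(orient="records"),
            "anova": {"F": F, "df1": df1, "df2": df2, "p": p},
            "pairwise": pw.to_dict(orient="records"),
        }
        if table["porosity"].notna().sum() >= 3:
            r, pr, n = pearson_corr(table["porosity"], table[col])
            report["correlations"][col] = {"vs": "porosity", "r": r,
                                           "p": pr, "n": n}

    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    _write_summary_md(out_dir / "summary.md", report, alpha)
    return table, report


def _write_summary_md(path: Path, report: dict, alpha: float) -> None:
    lines = ["# Regional cohort summary", "",
             f"_{report['note']}_", "",
             f"Specimens analysed: {report['n_specimens']}; "
             f"failures: {len(report['failures'])}", ""]
    for col, block in report["outcomes"].items():
        lines.append(f"## {block['label']}")
        lines.append("")
        lines.append("| region | n | mean | sd | 95% CI |")
        lines.append("|---|---|---|---|---|")
        for row in block["regions"]:
            lines.append(
                f"| {row['region']} | {row['n']} | {row['mean']:.3g} | "
                f"{row['sd']:.3g} | [{row['ci_low']:.3g}, {row['ci_high']:.3g}] |")
        a = block["anova"]
        lines.append("")
        lines.append(f"ANOVA: F({a['df1']}, {a['df2']}) = {a['F']:.3g}, "
                     f"p = {a['p']:.4g}")
        lines.append("")
        lines.append("| pair | t | p (raw) | p (Holm) | significant |")
        lines.append("|---|---|---|---|---|")
        for row in block["pairwise"]:
            sig = "yes" if row["p_holm"] < alpha else "no"
            lines.append(f"| {row['pair']} | {row['t']:.3g} | "
                         f"{row['p_raw']:.4g} | {row['p_holm']:.4g} | {sig} |")
        lines.append("")
    if report["correlations"]:
        lines.append("## Pooled correlations with porosity")
        lines.append("")
        lines.append("| outcome | r | p | n |")
        lines.append("|---|---|---|---|")
        for col, c in report["correlations"].items():
            lines.append(f"| {col} | {c['r']:.3g} | {c['p']:.4g} | {c['n']} |")
        lines.append("")
    path.write_text("\n".join(lines))
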