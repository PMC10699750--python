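"""Group tables, recovery comparison and the cross-species comparison.

Group summaries report mean +/- 1 SEM per parameter per temperature with
Welch-test significance letters (two groups: a shared letter means not
significantly different at alpha = 0.05, no multiplicity adjustment).  Every
number in an emitted table is re-derivable from the per-fish trait rows.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .published import SpeciesComparison
from .stats import ALPHA, paired_t, welch_t
from .types import TraitSummary

#: trait fields summarised in the group table
GROUP_PARAMETERS = (
    "ucrit_raw", "ucrit_corrected", "smr", "rmr", "mmr", "aas", "fas",
    "aas_r", "fas_r", "fh_rest", "fh_max", "fh_scope", "fh_fscope",
    "vs_rest", "vs_max", "vs_scope", "q_rest", "q_max", "q_scope",
    "ext_rest", "ext_max", "ext_scope", "rvm_pct",
)

#: rest / 2-h recovery parameter pairs
RECOVERY_PAIRS = (
    ("mo2", "rmr", "mo2_2h"),
    ("fh", "fh_rest", "fh_2h"),
    ("vs", "vs_rest", "vs_2h"),
    ("q", "q_rest", "q_2h"),
    ("ext", "ext_rest", "ext_2h"),
)

#: printed precision by parameter family (decimals)
_ROUND_RULES = (
    (("vs", "ext"), 3),
    (("fh",), 1),
)


def report_decimals(parameter: str) -> int:
    for prefixes, dec in _ROUND_RULES:
        if any(parameter.startswith(p) for p in prefixes):
            return dec
    return 2


def trait_frame(summaries: list[TraitSummary]) -> pd.DataFrame:
    """Per-fish trait rows as a DataFrame (flags joined with ';')."""
    rows = []
    for s in summaries:
        d = dataclasses.asdict(s)
        d["flags"] = ";".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def _mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    v = values[~np.isnan(values)]
    n = v.size
    if n == 0:
        return math.nan, math.nan, 0
    sem = float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return float(v.mean()), sem, n


def build_group_table(
    summaries: list[TraitSummary],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Mean +/- SEM per parameter per temperature group with Welch letters.

    The per-parameter n may drop below the group n when a fish lacks that
    measurement (e.g. no ventricle mass).
    """
    df = trait_frame(summaries)
    temps = sorted(df["temp_c"].unique())
    if any((df["temp_c"] == t).sum() < 2 for t in temps) or df.empty:
        raise InsufficientDataError("need >= 2 fish in every group")
    rows = []
    for param in GROUP_PARAMETERS:
        row: dict = {"parameter": param}
        groups = {}
        for t in temps:
            vals = df.loc[df["temp_c"] == t, param].to_numpy(dtype=float)
            mean, sem, n = _mean_sem(vals)
            key = f"{int(round(t))}C"
            row[f"mean_{key}"], row[f"sem_{key}"], row[f"n_{key}"] = mean, sem, n
            groups[t] = vals[~np.isnan(vals)]
        if len(temps) == 2 and all(g.size >= 2 for g in groups.values()):
            res = welch_t(groups[temps[0]], groups[temps[1]])
            row["welch_t"], row["welch_df"], row["p_value"] = (
                res.statistic, res.df, res.p_value)
            sig = res.p_value < alpha
            row[f"letter_{int(round(temps[0]))}C"] = "a"
            row[f"letter_{int(round(temps[1]))}C"] = "b" if sig else "a"
        rows.append(row)
    return pd.DataFrame(rows)


def build_recovery_table(
    summaries: list[TraitSummary],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Rest vs 2-h recovery means +/- SEM per temperature with paired t.

    Fish without a recovery window contribute to the rest column only and are
    excluded from the paired test (flagged via the n columns).
    """
    df = trait_frame(summaries)
    rows = []
    for t in sorted(df["temp_c"].unique()):
        sub = df[df["temp_c"] == t]
        for name, rest_col, rec_col in RECOVERY_PAIRS:
            rest = sub[rest_col].to_numpy(dtype=float)
            rec = sub[rec_col].to_numpy(dtype=float)
            m_r, s_r, n_r = _mean_sem(rest)
            m_c, s_c, n_c = _mean_sem(rec)
            row = {
                "temp_c": t, "parameter": name,
                "rest_mean": m_r, "rest_sem": s_r, "rest_n": n_r,
                "recovery_2h_mean": m_c, "recovery_2h_sem": s_c,
                "recovery_2h_n": n_c,
            }
            paired_mask = ~np.isnan(rest) & ~np.isnan(rec)
            if paired_mask.sum() >= 2:
                res = paired_t(rest[paired_mask], rec[paired_mask])
                row["paired_t"], row["p_value"] = res.statistic, res.p_value
                row["significant"] = res.p_value < alpha
            rows.append(row)
    return pd.DataFrame(rows)


def compare_species(
    focal: dict[str, float],
    reference: SpeciesComparison,
) -> dict[str, float]:
    """Fold differences (reference / focal) for the shared parameters."""
    out = {}
    for param in ("smr", "mmr", "aas", "fas", "ucrit"):
        ref = getattr(reference, param)
        foc = focal.get(param)
        if ref is None or foc in (None, 0) or (isinstance(foc, float) and math.isnan(foc)):
            out[param] = math.nan
        else:
            out[param] = ref / foc
    return out


def round_for_report(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the printed-precision rounding rules to a group table."""
    out = table.copy()
    for i, row in out.iterrows():
        dec = report_decimals(str(row["parameter"]))
        for col in out.columns:
            if col.startswith(("mean_", "sem_", "rest_", "recovery_")) and \
                    isinstance(row[col], float):
                out.at[i, col] = round(row[col], dec)
    return out


def write_table(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "md":
        path.write_text(table.to_markdown(index=False) + "\n")
    else:
        raise InsufficientDataError(f"unknown format {fmt!r}")
    return path


def plot_summary(group_table: pd.DataFrame, path: str | Path) -> Path:
    """Plain multi-panel plot of rest/max/scope values per temperature."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("fh", "fH (beats min-1)"), ("mmr", "MO2 (mg O2 kg-1 h-1)"),
              ("vs", "VS (ml kg-1)"), ("ext", "MO2/Q (mg O2 ml-1)"),
              ("q", "Q (ml min-1 kg-1)")]
    temps = sorted({c.split("_")[1] for c in group_table.columns
                    if c.startswith("mean_")})
    fig, axes = plt.subplots(3, 2, figsize=(8, 9))
    for ax, (prefix, label) in zip(axes.ravel(), panels):
        sub = group_table[group_table["parameter"].str.startswith(prefix)]
        x = np.arange(len(sub))
        for off, t in zip((-0.15, 0.15), temps):
            ax.errorbar(x + off, sub[f"mean_{t}"], yerr=sub[f"sem_{t}"],
                        fmt="o", capsize=3, label=t)
        ax.set_xticks(x, sub["parameter"], rotation=45, fontsize=7)
        ax.set_ylabel(label, fontsize=8)
        ax.legend(fontsize=7)
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
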