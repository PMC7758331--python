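"""Spike fertility statistics: seed set, potential spikelet productivity,
and multi-line trait comparison by one-way ANOVA with Fisher's protected LSD.

Seed set scores only florets 1 and 2 of each developed spikelet, so the
denominator is twice the developed-spikelet count.  Potential spikelet
productivity relates grains at harvest maturity to floret primordia counted
at the terminal-spikelet stage in the same spikelet position (basal, central,
apical).  Line-versus-control significance flags follow the protected-LSD
convention: pairwise tests are made only when the omnibus F test rejects, at
the same level, and a line is flagged at the smallest level at which its mean
difference from the control exceeds the least significant difference
``t_{1-a/2, df_e} * sqrt(MSE * (1/n_i + 1/n_c))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FLAGS = {0.05: "*", 0.01: "**"}


def seed_set(grains_f1f2: float, developed_spikelets: float) -> float:
    """Percent seed set in florets 1 and 2 of developed spikelets, capped at 100."""
    if developed_spikelets <= 0:
        raise ZeroDivisionError(
            "seed set undefined: developed_spikelets must be positive"
        )
    if grains_f1f2 < 0:
        raise ValueError("grain count must be non-negative")
    return min(100.0, 100.0 * grains_f1f2 / (2.0 * developed_spikelets))


def potential_productivity(grains_at_hm: float, primordia_at_ts: float) -> float:
    """Percent of floret primordia (terminal-spikelet stage) that produced
    grains by harvest maturity, per spikelet position."""
    if primordia_at_ts <= 0:
        raise ZeroDivisionError(
            "potential productivity undefined: primordia_at_ts must be positive"
        )
    if grains_at_hm < 0:
        raise ValueError("grain count must be non-negative")
    return 100.0 * grains_at_hm / primordia_at_ts


def productivity_table(spikelet_table: pd.DataFrame) -> pd.DataFrame:
    """Per line x position potential productivity from a spikelet-position
    table with columns (line, position, stage, primordia_per_spikelet,
    grains)."""
    ts = spikelet_table[spikelet_table["stage"] == "terminal_spikelet"]
    hm = spikelet_table[spikelet_table["stage"] == "harvest_maturity"]
    merged = pd.merge(
        ts[["line", "position", "primordia_per_spikelet"]],
        hm[["line", "position", "grains"]],
        on=["line", "position"],
    )
    merged["potential_productivity"] = [
        potential_productivity(g, p)
        for g, p in zip(merged["grains"], merged["primordia_per_spikelet"])
    ]
    return merged[["line", "position", "potential_productivity"]]


@dataclass
class AnovaLsdResult:
    """Per-trait omnibus statistics and line-vs-control flags."""

    flags: pd.DataFrame  # index: line, columns: trait -> "", "*", "**"
    means: pd.DataFrame  # index: line, columns: trait
    omnibus: pd.DataFrame  # index: trait, columns: F, pvalue, df_between, df_error, mse
    control: str
    excluded: dict[str, str] = field(default_factory=dict)


def anova_lsd(
    obs: pd.DataFrame,
    control: str,
    alphas: Sequence[float] = (0.05, 0.01),
    bonferroni: bool = False,
) -> AnovaLsdResult:
    """One-way ANOVA per trait with protected-LSD flags against a control line.

    ``obs`` is long-format with columns (line, replicate, trait, value).
    Lines with fewer than two replicates for a trait are excluded from that
    trait with a warning.  With ``bonferroni=True`` the pairwise levels are
    divided by the number of comparisons (off by default, matching the usual
    LSD reporting style).
    """
    required = {"line", "trait", "value"}
    if not required.issubset(obs.columns):
        raise ValueError(f"obs must have columns {sorted(required)}")
    if control not in set(obs["line"]):
        raise ValueError(f"control line {control!r} absent from observations")
    alphas = sorted(alphas, reverse=True)  # e.g. [0.05, 0.01]

    traits = list(dict.fromkeys(obs["trait"]))
    lines = list(dict.fromkeys(obs["line"]))
    flags = pd.DataFrame("", index=lines, columns=traits, dtype=object)
    means = pd.DataFrame(np.nan, index=lines, columns=traits, dtype=float)
    omni_rows = {}
    excluded: dict[str, str] = {}

    for trait in traits:
        sub = obs[obs["trait"] == trait]
        groups: dict[str, np.ndarray] = {}
        for line in lines:
            vals = sub.loc[sub["line"] == line, "value"].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            if len(vals) < 2:
                excluded[line] = f"fewer than 2 replicates for {trait}"
                warnings.warn(
                    f"line {line!r} excluded from {trait}: fewer than 2 replicates"
                )
                continue
            groups[line] = vals
            means.loc[line, trait] = vals.mean()
        if control not in groups:
            raise ValueError(f"control line {control!r} unusable for trait {trait!r}")
        k = len(groups)
        n_total = sum(len(v) for v in groups.values())
        grand = np.concatenate(list(groups.values())).mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        df_b, df_e = k - 1, n_total - k
        if df_b == 0 or df_e == 0:
            omni_rows[trait] = (np.nan, np.nan, df_b, df_e, np.nan)
            continue
        mse = ss_within / df_e
        if mse == 0:
            # all groups internally constant: infinite F when any mean differs
            distinct = len({v.mean() for v in groups.values()}) > 1
            F, p = (np.inf, 0.0) if distinct else (0.0, 1.0)
        else:
            F = (ss_between / df_b) / mse
            p = float(stats.f.sf(F, df_b, df_e))
        omni_rows[trait] = (F, p, df_b, df_e, mse)

        n_comp = max(1, k - 1)
        nc = len(groups[control])
        mc = groups[control].mean()
        for line, vals in groups.items():
            if line == control:
                continue
            diff = abs(vals.mean() - mc)
            flag = ""
            for alpha in sorted(alphas):  # smallest alpha first wins
                if p > alpha:
                    continue
                pair_alpha = alpha / n_comp if bonferroni else alpha
                if mse == 0:
                    exceed = diff > 0
                else:
                    tcrit = stats.t.ppf(1 - pair_alpha / 2, df_e)
                    lsd = tcrit * np.sqrt(mse * (1 / len(vals) + 1 / nc))
                    exceed = diff > lsd
                if exceed:
                    flag = FLAGS.get(alpha, "*")
                    break
            flags.loc[line, trait] = flag
    omnibus = pd.DataFrame.from_dict(
        omni_rows,
        orient="index",
        columns=["F", "pvalue", "df_between", "df_error", "mse"],
    )
    return AnovaLsdResult(
        flags=flags, means=means, omnibus=omnibus, control=control, excluded=excluded
    )


def summarize_panel(
    obs: pd.DataFrame,
    control: str,
    viability: dict[str, str] | None = None,
    alphas: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Per-line trait means with significance flags versus the control, plus
    an optional viability column, in deterministic (input) line order."""
    res = anova_lsd(obs, control, alphas=alphas)
    traits = list(res.means.columns)
    out = pd.DataFrame(index=res.means.index)
    out.index.name = "line"
    for trait in traits:
        out[trait] = res.means[trait]
        out[f"{trait}_flag"] = res.flags[trait]
    if viability is not None:
        out["viability"] = [viability.get(line, "unknown") for line in out.index]
    return out.reset_index()


def report_to_markdown(report: pd.DataFrame) -> str:
    """Plain GitHub-style markdown rendering of a summary table."""
    cols = list(report.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in report.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.1f}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
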