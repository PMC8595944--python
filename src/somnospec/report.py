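"""Cohort summaries and severity-group comparisons.

Continuous variables are summarized as median (interquartile range) per
severity group and compared pairwise with two-sided Mann-Whitney U tests;
sex is compared with Fisher's exact test.  The three pairwise comparisons
are labelled a (controls vs mild), b (controls vs moderate/severe) and
c (mild vs moderate/severe).  No multiple-testing correction is applied by
default (raw p < 0.05 flags); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import COGNITIVE_VARIABLES, PSG_VARIABLES
from .synthetic import GROUP_LABELS

PAIRWISE = (
    ("a", "controls", "mild"),
    ("b", "controls", "moderate_severe"),
    ("c", "mild", "moderate_severe"),
)


def severity_group(ahi: float) -> str:
    """Severity group from the apnea-hypopnea index (events/hour).

    ``AHI <= 1`` controls; ``1 < AHI < 5`` mild; ``AHI >= 5``
    moderate/severe.
    """
    if ahi < 0:
        raise ValueError(f"AHI must be >= 0, got {ahi}")
    if ahi <= 1.0:
        return "controls"
    if ahi < 5.0:
        return "mild"
    return "moderate_severe"


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and pooled.size <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


@dataclasses.dataclass
class GroupComparison:
    variable: str
    test: str  # "mann-whitney" or "fisher"
    summaries: dict[str, str]  # per-group "median (q1, q3)" or counts
    p_values: dict[str, float]  # keys "a", "b", "c"
    significant: dict[str, bool]

    def flags(self, alpha: float = 0.05) -> str:
        keys = [k for k, p in sorted(self.p_values.items()) if p < alpha]
        return ", ".join(keys) if keys else "n.s."


def _summary(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def compare_groups(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> list[GroupComparison]:
    """Pairwise severity-group comparisons for every cohort variable.

    Skips (with a ``NaN`` p-value) any pair involving a group with fewer
    than 2 subjects.  The result is a pure function of ``table``.
    """
    if variables is None:
        variables = ["age"] + list(PSG_VARIABLES) + list(COGNITIVE_VARIABLES)
    groups = {g: table[table["group"] == g] for g in GROUP_LABELS}
    comparisons: list[GroupComparison] = []

    if "sex" in table.columns:
        counts = {
            g: (int((rows["sex"] == "M").sum()), int((rows["sex"] == "F").sum()))
            for g, rows in groups.items()
        }
        p_values = {}
        for key, g1, g2 in PAIRWISE:
            if len(groups[g1]) < 2 or len(groups[g2]) < 2:
                p_values[key] = float("nan")
                continue
            p_values[key] = fisher_exact_p([counts[g1], counts[g2]])
        comparisons.append(
            GroupComparison(
                variable="sex",
                test="fisher",
                summaries={g: f"{m}/{f}" for g, (m, f) in counts.items()},
                p_values=p_values,
                significant={k: p < alpha for k, p in p_values.items()},
            )
        )

    for var in variables:
        if var not in table.columns:
            continue
        p_values = {}
        for key, g1, g2 in PAIRWISE:
            a, b = groups[g1][var].dropna(), groups[g2][var].dropna()
            if len(a) < 2 or len(b) < 2:
                p_values[key] = float("nan")
                continue
            p_values[key] = mann_whitney_p(a.to_numpy(), b.to_numpy())
        comparisons.append(
            GroupComparison(
                variable=var,
                test="mann-whitney",
                summaries={
                    g: _summary(rows[var].dropna().to_numpy())
                    for g, rows in groups.items()
                    if len(rows)
                },
                p_values=p_values,
                significant={k: p < alpha for k, p in p_values.items()},
            )
        )

    if benjamini_hochberg:
        flat = [
            (i, k, p)
            for i, comp in enumerate(comparisons)
            for k, p in comp.p_values.items()
            if np.isfinite(p)
        ]
        order = sorted(range(len(flat)), key=lambda j: flat[j][2])
        m = len(flat)
        adjusted = [0.0] * m
        prev = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            j = order[rank_from_top]
            adj = min(prev, flat[j][2] * m / (rank_from_top + 1))
            adjusted[j] = adj
            prev = adj
        for (i, k, _), adj in zip(flat, adjusted):
            comparisons[i].significant[k] = adj < alpha
    return comparisons


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for comp in comparisons:
        row = {"variable": comp.variable, "test": comp.test}
        for g in GROUP_LABELS:
            row[g] = comp.summaries.get(g, "")
        for key, _, _ in PAIRWISE:
            row[f"p_{key}"] = comp.p_values.get(key, float("nan"))
        row["significant"] = comp.flags()
        rows.append(row)
    return pd.DataFrame(rows)


def report_markdown(comparisons: list[GroupComparison]) -> str:
    """Render the comparison table as Markdown (deterministic for a given
    feature table)."""
    frame = comparisons_to_frame(comparisons)
    lines = [
        "# Cohort summary by apnea severity group",
        "",
        "Median (Q1, Q3) per group; pairwise two-sided Mann-Whitney U tests",
        "(Fisher's exact for sex): a = controls vs mild, b = controls vs",
        "moderate/severe, c = mild vs moderate/severe.",
        "",
        "| Variable | Controls | Mild | Moderate/severe | p_a | p_b | p_c | p<0.05 |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, row in frame.iterrows():
        lines.append(
            "| {variable} | {controls} | {mild} | {moderate_severe} | "
            "{p_a:.3g} | {p_b:.3g} | {p_c:.3g} | {significant} |".format(**row)
        )
    return "\n".join(lines) + "\n"


def write_report(
    comparisons: list[GroupComparison], out_dir: str | Path
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    md = out_dir / "report.md"
    csv = out_dir / "report.csv"
    md.write_text(report_markdown(comparisons))
    comparisons_to_frame(comparisons).to_csv(csv, index=False)
    return md, csv
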