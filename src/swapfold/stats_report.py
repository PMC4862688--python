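"""Rank-correlation analysis linking permutant properties to misfolding
populations, and binomial population errors.

The central empirical observation is that the *stability* ΔG_s of the
isolated folded/misfolded domain — not its folding barrier ΔG_f or
relative contact order — rank-correlates with how often the corresponding
final state is reached in tandem-dimer folding campaigns.  A packaged
reference propensity table (simulated populations and domain properties
for SH3, PDZ, TNfn3, UBQ, SH2, Titin I27 and GB1 permutants) ships with
the module so the correlation analysis can be exercised and checked
without any simulation.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from scipy import stats as sps

#: proteins for which the fixture table carries population variation
BRACKETED_PROTEINS = ("SH3", "PDZ", "TNfn3", "SH2", "TitinI27")
PROPERTY_COLUMNS = ("RCO", "dG_f", "dG_s")


def load_reference_table() -> pd.DataFrame:
    """The packaged propensity table (provenance column marks fixture rows)."""
    with importlib.resources.files("swapfold.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-rank (fractional) tie handling.

    Returns NaN (with no exception) for constant input, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def population_summary(outcomes: pd.DataFrame, n: int | None = None) -> pd.DataFrame:
    """Per-label fraction and binomial standard error SE = sqrt(p(1−p)/n)."""
    if "final_label" not in outcomes:
        raise ValueError("outcomes table needs a final_label column")
    if n is None:
        n = len(outcomes)
    counts = outcomes["final_label"].value_counts()
    df = pd.DataFrame({"label": counts.index, "count": counts.values})
    df["fraction"] = df["count"] / n
    df["stderr"] = np.sqrt(df["fraction"] * (1 - df["fraction"]) / n)
    return df


def binomial_se(p: float, n: int) -> float:
    """Standard error of a population fraction, as a fraction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.sqrt(p * (1 - p) / n))


def worst_case_se_percent(n: int) -> float:
    """Maximum SE over p (at p = 0.5), in percent."""
    return 100.0 * binomial_se(0.5, n)


def correlation_report(table: pd.DataFrame, round_to: int | None = None) -> pd.DataFrame:
    """Per-protein Spearman ρ of RCO, ΔG_f and ΔG_s against population.

    Mirrors the bracket layout of the reference table: one row per protein
    with at least three states, NaN where a column is constant.  Values are
    rounded only at presentation (``round_to``).
    """
    rows = []
    for protein, grp in table.groupby("protein", sort=False):
        if len(grp) < 3:
            continue
        row = {"protein": protein, "n_states": len(grp)}
        for col in PROPERTY_COLUMNS:
            row[f"rho_{col}"] = spearman(grp[col], grp["population"])
        rows.append(row)
    df = pd.DataFrame(rows)
    if round_to is not None:
        for col in df.columns:
            if col.startswith("rho_"):
                df[col] = df[col].round(round_to)
    return df


def propensity_table_from_campaign(
    summary: pd.DataFrame,
    protein: str,
    properties: dict,
) -> pd.DataFrame:
    """Assemble campaign fractions + per-K properties into table rows.

    ``properties`` maps K (0 for native) to a dict with RCO/dG_f/dG_s
    entries; populations come from the campaign summary fractions.
    """
    rows = []
    for K, props in properties.items():
        label = "native" if K == 0 else K
        sel = summary.loc[summary["label"] == label, "fraction"]
        pop = float(sel.iloc[0]) * 100.0 if len(sel) else 0.0
        rows.append({
            "protein": protein, "K": K,
            "RCO": props.get("RCO", np.nan),
            "dG_f": props.get("dG_f", np.nan),
            "dG_s": props.get("dG_s", np.nan),
            "population": pop,
            "provenance": "simulated",
        })
    df = pd.DataFrame(rows)
    if df["population"].sum() > 100.0 + 1e-9:
        raise ValueError("populations exceed 100%")
    return df
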