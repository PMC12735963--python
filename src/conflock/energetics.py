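"""Replicate-level statistics on MM/GBSA binding-energy component tables.

The binding free energies themselves are inputs (kcal/mol, one value per
system x replicate x component); this module provides the summary layer —
per-system mean +- sample SD — and independent two-sample t-tests between
systems, entered either from raw replicate values or directly from published
summary statistics (mean, SD, n).

The pooled-variance test is the default: with three replicates per system it
is the textbook small-sample comparison; Welch's unequal-variance variant is
available via ``method="welch"``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, LookupError_, ParameterError

COMPONENTS = ("dG_bind", "dE_vdW", "dE_Coulomb", "dG_Lipo", "dG_SolvGB", "E_StrainLig")

#: Published per-system MM/GBSA summaries (mean, sample SD, n replicates) for
#: the Sestrin2 / branched-chain-amino-acid systems, kcal/mol.  These are the
#: reference inputs for the summary-statistics entry points; the package does
#: not compute MM/GBSA energies.
SESN2_BCAA_SUMMARIES = {
    "leucine": {
        "dG_bind": (-37.60, 2.39, 3), "dE_vdW": (-28.09, 1.28, 3),
        "dE_Coulomb": (13.13, 3.33, 3), "dG_Lipo": (-8.25, 0.59, 3),
        "dG_SolvGB": (-12.30, 1.87, 3), "E_StrainLig": (0.66, 0.62, 3),
    },
    "isoleucine": {
        "dG_bind": (-34.47, 1.98, 3), "dE_vdW": (-25.92, 1.38, 3),
        "dE_Coulomb": (14.59, 2.89, 3), "dG_Lipo": (-7.42, 0.45, 3),
        "dG_SolvGB": (-13.12, 1.55, 3), "E_StrainLig": (0.52, 0.27, 3),
    },
    "valine": {
        "dG_bind": (-30.32, 3.18, 3), "dE_vdW": (-21.96, 1.29, 3),
        "dE_Coulomb": (11.27, 2.15, 3), "dG_Lipo": (-5.92, 0.61, 3),
        "dG_SolvGB": (-11.10, 1.93, 3), "E_StrainLig": (0.41, 0.32, 3),
    },
}


@dataclasses.dataclass
class EnergyReplicateTable:
    """Tidy per-replicate energy components: system, replicate, component, value."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"system", "replicate", "component", "value"}
        if not required.issubset(self.data.columns):
            raise ParameterError(f"table needs columns {sorted(required)}")
        bad = set(self.data["component"]) - set(COMPONENTS)
        if bad:
            raise ParameterError(f"unknown components: {sorted(bad)}")
        if not np.all(np.isfinite(self.data["value"])):
            raise ParameterError("energy values must be finite")

    @classmethod
    def from_csv(cls, path) -> "EnergyReplicateTable":
        return cls(pd.read_csv(path))

    def systems(self) -> list:
        return sorted(self.data["system"].unique())


@dataclasses.dataclass
class ComparisonResult:
    """Two-sample t-test between systems on one energy component."""

    system_a: str
    system_b: str
    component: str
    mean_diff: float     # mean_a - mean_b, kcal/mol
    t: float
    df: float
    p: float             # two-sided
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")
        if self.df <= 0:
            raise ValueError("non-positive degrees of freedom")


def summarize(table: EnergyReplicateTable) -> pd.DataFrame:
    """Per-system mean +- sample SD (n-1 denominator) per component.

    Raises :class:`DegeneracyError` when any system has a single replicate,
    since the SD is then undefined.
    """
    g = table.data.groupby(["system", "component"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, "system"].unique()
        raise DegeneracyError(f"single replicate for {list(bad)}: SD undefined")
    order = {c: i for i, c in enumerate(COMPONENTS)}
    out = out.sort_values(["system", "component"], key=lambda s: s.map(lambda v: order.get(v, v)))
    return out.reset_index(drop=True)


def ttest_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    method: str = "pooled",
    labels: tuple = ("A", "B"),
    component: str = "dG_bind",
) -> ComparisonResult:
    """Independent two-sample t-test from summary statistics.

    ``pooled`` uses sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2) with
    df = n1+n2-2; ``welch`` uses the Welch-Satterthwaite approximation.
    Identical summaries with zero variance give the t = 0, p = 1 convention;
    different means with zero variance are degenerate.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("both samples need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("SDs must be non-negative")
    diff = mean1 - mean2
    if method == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif method == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        if se > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    else:
        raise ParameterError(f"unknown method {method!r}")
    if se == 0:
        if diff == 0:
            return ComparisonResult(labels[0], labels[1], component, 0.0, 0.0, float(df), 1.0, method)
        raise DegeneracyError("zero variance with unequal means: t undefined")
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(labels[0], labels[1], component, float(diff), float(t), float(df), float(p), method)


def compare_systems(
    summary: pd.DataFrame,
    system_a: str,
    system_b: str,
    component: str = "dG_bind",
    method: str = "pooled",
) -> ComparisonResult:
    """t-test between two systems using a :func:`summarize`-style table."""
    rows = {}
    for sysname in (system_a, system_b):
        sel = summary[(summary["system"] == sysname) & (summary["component"] == component)]
        if sel.empty:
            raise LookupError_(f"no {component} entry for system {sysname!r}")
        rows[sysname] = sel.iloc[0]
    a, b = rows[system_a], rows[system_b]
    return ttest_from_summary(
        a["mean"], a["sd"], int(a["n"]), b["mean"], b["sd"], int(b["n"]),
        method=method, labels=(system_a, system_b), component=component,
    )


def mean_difference(summary: pd.DataFrame, system_a: str, system_b: str, component: str = "dG_bind") -> float:
    """|mean_A - mean_B| for one component, kcal/mol."""
    vals = {}
    for sysname in (system_a, system_b):
        sel = summary[(summary["system"] == sysname) & (summary["component"] == component)]
        if sel.empty:
            raise LookupError_(f"no {component} entry for system {sysname!r}")
        vals[sysname] = float(sel.iloc[0]["mean"])
    return abs(vals[system_a] - vals[system_b])


def summary_from_reference(reference: dict | None = None) -> pd.DataFrame:
    """Build a :func:`summarize`-style table from (mean, sd, n) summaries."""
    reference = reference if reference is not None else SESN2_BCAA_SUMMARIES
    rows = []
    for system, comps in reference.items():
        for comp, (mean, sd, n) in comps.items():
            rows.append({"system": system, "component": comp, "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows)


class BindingEnergyModel:
    """Replicate binding-energy statistics in a fit/results workflow.

    Construct from an :class:`EnergyReplicateTable` (raw replicate values) or
    via :meth:`from_summaries` when only published mean/SD/n are available.
    """

    def __init__(self, table: EnergyReplicateTable | None = None,
                 summary: pd.DataFrame | None = None) -> None:
        if (table is None) == (summary is None):
            raise ParameterError("provide exactly one of table or summary")
        self.table = table
        self._summary = summary

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BindingEnergyModel":
        return cls(table=EnergyReplicateTable(df))

    @classmethod
    def from_summaries(cls, reference: dict | None = None) -> "BindingEnergyModel":
        return cls(summary=summary_from_reference(reference))

    def fit(self, method: str = "pooled") -> "EnergeticsResults":
        summary = summarize(self.table) if self.table is not None else self._summary
        return EnergeticsResults(summary, method)


class EnergeticsResults:
    """Per-system component summaries with pairwise significance tests."""

    def __init__(self, summary: pd.DataFrame, method: str = "pooled") -> None:
        self.summary_table = summary
        self.method = method

    def compare(self, system_a: str, system_b: str, component: str = "dG_bind") -> ComparisonResult:
        return compare_systems(self.summary_table, system_a, system_b, component, self.method)

    def mean_difference(self, system_a: str, system_b: str, component: str = "dG_bind") -> float:
        return mean_difference(self.summary_table, system_a, system_b, component)

    def summary(self) -> str:
        systems = sorted(self.summary_table["system"].unique())
        lines = ["Binding free-energy components (kcal/mol, mean +- SD)",
                 "=" * 56,
                 "component     " + "".join(f"{s:>18s}" for s in systems)]
        for comp in COMPONENTS:
            cells = []
            for s in systems:
                sel = self.summary_table[
                    (self.summary_table["system"] == s) & (self.summary_table["component"] == comp)
                ]
                cells.append(
                    f"{sel.iloc[0]['mean']:8.2f} +- {sel.iloc[0]['sd']:4.2f}" if not sel.empty else " " * 16
                )
            lines.append(f"{comp:<12s}" + "".join(f"{c:>18s}" for c in cells))
        return "\n".join(lines)
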