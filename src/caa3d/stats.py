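"""Nonparametric test battery and group reports.

Continuous quantities are summarized as quartiles (median and 25th–75th
percentiles).  Two groups are compared by the Mann–Whitney U test, three
or more by Kruskal–Wallis followed by all-pairs Steel–Dwass multiple
comparisons.  The significance level throughout is α = 0.05.

Mann–Whitney and Kruskal–Wallis delegate to scipy (exact enumeration for
small tie-free Mann–Whitney samples, tie-corrected normal/χ² otherwise).
Steel–Dwass is implemented here: for each unordered pair of groups only
that pair's pooled data are ranked (mid-ranks), the tie-corrected
standardized Mann–Whitney statistic z is formed, and the two-sided
p-value is P(Q_{k,∞} ≥ |z|·√2) under the studentized-range distribution
with k groups and infinite degrees of freedom — the classic asymptotic
used by JMP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple[int, ...]
    tie_correction: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "group_sizes": list(self.group_sizes),
            "tie_correction": self.tie_correction,
        }


@dataclass
class PairwiseTable:
    rows: list[tuple[str, str, float, float]]  # (a, b, standardized z, p)

    def to_dict(self) -> list[dict[str, Any]]:
        return [
            {"group_a": a, "group_b": b, "z": z, "p_value": p}
            for a, b, z, p in self.rows
        ]


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q25, q75) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quartiles of empty input")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return float(med), float(q25), float(q75)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann–Whitney U.

    ``mode='auto'`` uses exact enumeration when both n ≤ 8 and there are
    no ties, otherwise the tie-corrected normal approximation with
    continuity correction.  Identical pooled values give p = 1 with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return TestResult(
            statistic=a.size * b.size / 2.0,
            p_value=1.0,
            method="mann-whitney-u (degenerate)",
            group_sizes=(a.size, b.size),
        )
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann-whitney-u ({method})",
        group_sizes=(a.size, b.size),
        tie_correction=has_ties and method == "asymptotic",
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with χ²(k−1) p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size == 0 for g in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; H = 0, p = 1")
        return TestResult(0.0, 1.0, "kruskal-wallis (degenerate)",
                          tuple(g.size for g in arrays))
    h, p = sps.kruskal(*arrays)
    has_ties = np.unique(pooled).size < pooled.size
    return TestResult(
        statistic=float(h),
        p_value=float(p),
        method="kruskal-wallis",
        group_sizes=tuple(g.size for g in arrays),
        tie_correction=has_ties,
    )


def pairwise_mw_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected standardized Mann–Whitney statistic for one pair,
    ranking only that pair's pooled data (no continuity correction)."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((u - mean) / np.sqrt(var))


def steel_dwass(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> PairwiseTable:
    """All-pairs Steel–Dwass multiple comparisons.

    For each unordered pair the standardized pairwise Mann–Whitney z is
    referred to the studentized-range distribution:
    p = P(Q_{k,∞} ≥ |z|·√2).  At k = 2 this reduces to the two-sided
    normal-approximation Mann–Whitney test.
    """
    if isinstance(groups, Mapping):
        named = [(str(k), np.asarray(v, dtype=float)) for k, v in groups.items()]
    else:
        named = [(f"group{i}", np.asarray(g, dtype=float)) for i, g in enumerate(groups)]
    if len(named) < 2:
        raise ValueError("need >= 2 groups")
    for name, g in named:
        if g.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    k = len(named)
    rows: list[tuple[str, str, float, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            (na, a), (nb, b) = named[i], named[j]
            z = pairwise_mw_z(a, b)
            p = float(sps.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
            rows.append((na, nb, z, min(max(p, 0.0), 1.0)))
    return PairwiseTable(rows=rows)


# ----------------------------------------------------------------------
# report assembly
# ----------------------------------------------------------------------

def _summary(values: np.ndarray) -> dict[str, Any]:
    med, q25, q75 = quartiles(values)
    return {"n": int(values.size), "median": med, "q25": q25, "q75": q75}


def compare_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, Any]:
    """Quartile summaries plus the test appropriate for the group count:
    nothing for one group, Mann–Whitney for two, Kruskal–Wallis followed by
    Steel–Dwass for three or more."""
    clean = {
        str(k): np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for k, v in groups.items()
    }
    clean = {k: v for k, v in clean.items() if v.size > 0}
    out: dict[str, Any] = {
        "groups": {k: _summary(v) for k, v in clean.items()},
    }
    testable = {k: v for k, v in clean.items() if v.size >= 2}
    if len(testable) == 2:
        a, b = testable.values()
        out["test"] = mann_whitney_u(a, b).to_dict()
    elif len(testable) >= 3:
        out["test"] = kruskal_wallis(list(testable.values())).to_dict()
        out["pairwise"] = steel_dwass(testable).to_dict()
    return out


def build_report(samples: "Sequence[Any]", metadata: Mapping[int, Mapping[str, Any]] | None = None) -> dict[str, Any]:
    """Assemble the grouped report over per-sample summaries.

    ``samples`` are :class:`~caa3d.pipeline.SampleSummary` objects; group
    comparisons cover D0 diameters (Aβ+ vs Aβ−, overall and by region /
    load class / CAA type), perivascular densities (the same groupings,
    plus load classes via Kruskal–Wallis + Steel–Dwass), per-segment load
    rates, and SMA-onset label distributions.
    """
    import pandas as pd

    units = pd.concat([s.unit_table for s in samples], ignore_index=True)
    report: dict[str, Any] = {"schema_version": 1, "n_samples": len(samples)}

    def by_status(frame, column) -> dict[str, Any]:
        return compare_groups(
            {
                "abeta_pos": frame.loc[frame.abeta_positive, column],
                "abeta_neg": frame.loc[~frame.abeta_positive, column],
            }
        )

    diam = units.dropna(subset=["d0_diameter_um"])
    report["d0_diameter_um"] = {"overall": by_status(diam, "d0_diameter_um")}
    for key in ("region", "load_class", "caa_type"):
        report["d0_diameter_um"][f"by_{key}"] = {
            str(val): by_status(sub, "d0_diameter_um")
            for val, sub in diam.groupby(key)
        }

    dens = units.dropna(subset=["density_per_um"])
    report["density_per_um"] = {"overall": by_status(dens, "density_per_um")}
    for key in ("region", "caa_type"):
        report["density_per_um"][f"by_{key}"] = {
            str(val): by_status(sub, "density_per_um")
            for val, sub in dens.groupby(key)
        }
    if dens.load_class.nunique() >= 2:
        report["density_per_um"]["by_load_class"] = compare_groups(
            {str(k): v.density_per_um for k, v in dens.groupby("load_class")}
        )

    report["samples"] = {
        str(s.sample_id): {
            "region": s.region,
            "caa_type": s.caa_type,
            "load": s.load_summary.to_dict(),
            "sma_onset_counts": s.sma_onset_counts,
            "dyshoric_fraction": s.dyshoric_fraction,
        }
        for s in samples
    }
    return report
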