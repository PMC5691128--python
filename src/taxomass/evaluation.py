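"""Validation metrics for mock-community benchmarks.

Specificity/sensitivity of the filtering strategies, signed x-fold deviation
of measured taxon fractions from known community inputs, detection counts,
and between-method significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .inference import ProteinGroup, StrategyResult
from .quant import AMBIGUOUS, TaxonAbundanceTable, _group_taxon
from .seqdb import TaxonomyTree

CONVENTIONS = ("ratio", "centered")


@dataclass
class CommunityTruth:
    """Known per-taxon input fractions of a mock community."""

    df: pd.DataFrame  # taxon_id, input_protein_fraction, input_cell_fraction

    def __post_init__(self) -> None:
        for col in ("input_protein_fraction", "input_cell_fraction"):
            if col not in self.df.columns:
                raise ValueError(f"truth table missing column {col!r}")
            vals = self.df[col].to_numpy(dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative values in {col}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{col} must sum to 1 (got {vals.sum():.12f})")

    def protein_fractions(self) -> dict[str, float]:
        return dict(zip(self.df["taxon_id"], self.df["input_protein_fraction"]))

    def taxa(self) -> list[str]:
        return list(self.df["taxon_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CommunityTruth":
        return cls(pd.read_csv(path, sep="\t", dtype={"taxon_id": str}))


def fold_deviation(measured: float, input_fraction: float, convention: str = "ratio") -> float:
    """Signed symmetric fold change of a measurement from its known input.

    ``ratio``: measured/input when measured >= input, else -(input/measured);
    equality gives 1.  ``centered`` subtracts the sign unit so equality gives
    0.  Undetected taxa (measured = 0) are a detection question, not a
    deviation one, and are rejected here.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; valid: {CONVENTIONS}")
    if input_fraction <= 0:
        raise ValueError("input fraction must be positive (taxon missing from truth?)")
    if measured <= 0:
        raise ValueError("measured fraction must be positive (undetected taxa are excluded)")
    if measured >= input_fraction:
        d = measured / input_fraction
    else:
        d = -(input_fraction / measured)
    if convention == "centered":
        d = d - np.sign(d)
    return float(d)


def deviation_report(
    measured: Mapping[str, float],
    truth: CommunityTruth,
    convention: str = "ratio",
) -> pd.DataFrame:
    """Per-taxon fold deviations for every truth taxon detected in
    *measured* (zeros removed), with input and measured fractions."""
    rows = []
    for taxon, inp in truth.protein_fractions().items():
        m = measured.get(taxon, 0.0)
        if m <= 0 or inp <= 0:
            continue
        rows.append(
            (taxon, inp, m, fold_deviation(m, inp, convention))
        )
    return pd.DataFrame(
        rows, columns=["taxon_id", "input_fraction", "measured_fraction", "deviation"]
    )


def deviation_summary(deviations: Iterable[float]) -> dict[str, float]:
    arr = np.asarray(list(deviations), dtype=float)
    if arr.size == 0:
        raise ValueError("no deviations to summarize")
    return {
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
        "p10": float(np.percentile(arr, 10)),
        "p90": float(np.percentile(arr, 90)),
        "n": int(arr.size),
    }


def specificity(table: TaxonAbundanceTable, expected_taxa: Iterable[str]) -> float:
    """Fraction of quantified signal attributed to the expected taxa.

    Ambiguous-group signal counts against specificity (it is not attributed
    to any single organism).
    """
    expected = set(expected_taxa)
    total = float(table.df["raw"].sum()) + table.ambiguous_raw
    if total <= 0:
        raise ValueError("abundance table carries no signal")
    hit = float(table.df.loc[table.df["taxon_id"].isin(expected), "raw"].sum())
    return hit / total


def sensitivity(
    strategy_result: StrategyResult,
    groups: list[ProteinGroup],
    target_taxon: str,
    tree: Optional[TaxonomyTree] = None,
    rank: Optional[str] = None,
) -> int:
    """Number of accepted groups attributed (unambiguously) to the target
    taxon at the working rank."""
    count = 0
    for g in groups:
        if g.group_id not in strategy_result.accepted:
            continue
        if _group_taxon(g, tree, rank) == target_taxon:
            count += 1
    return count


def detection_summary(
    group_taxa: Mapping[str, str],
    group_counts: Mapping[str, int],
    truth: CommunityTruth,
    min_groups: int = 1,
) -> tuple[int, pd.DataFrame]:
    """Detected taxa: those with at least *min_groups* accepted groups
    carrying at least one assigned PSM."""
    per_taxon: dict[str, int] = {t: 0 for t in truth.taxa()}
    for gid, taxon in group_taxa.items():
        if taxon == AMBIGUOUS:
            continue
        if group_counts.get(gid, 0) >= 1 and taxon in per_taxon:
            per_taxon[taxon] += 1
    df = pd.DataFrame(
        {
            "taxon_id": list(per_taxon),
            "n_groups": list(per_taxon.values()),
        }
    )
    df["detected"] = df["n_groups"] >= min_groups
    return int(df["detected"].sum()), df


def compare_methods(
    deviations: Mapping[str, Iterable[float]], alpha: float = 0.01
) -> pd.DataFrame:
    """Pairwise Welch t-tests on absolute centered deviations per method.

    Returns one row per ordered pair with means and p-value, plus a
    ``flagged`` column marking the method with the significantly lowest mean
    absolute deviation (significant against every other method).
    """
    sets = {name: np.abs(np.asarray(list(v), dtype=float)) for name, v in deviations.items()}
    for name, arr in sets.items():
        if arr.size < 2:
            raise ValueError(f"method {name!r} has fewer than two deviations")
    names = sorted(sets)
    rows = []
    pvals: dict[tuple[str, str], float] = {}
    for a in names:
        for b in names:
            if a >= b:
                continue
            x, y = sets[a], sets[b]
            if x.size == y.size and np.allclose(np.sort(x), np.sort(y)):
                p = 1.0
            else:
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            pvals[(a, b)] = pvals[(b, a)] = p
            rows.append((a, b, float(x.mean()), float(y.mean()), p))
    out = pd.DataFrame(
        rows, columns=["method_a", "method_b", "mean_abs_a", "mean_abs_b", "p_value"]
    )
    means = {n: sets[n].mean() for n in names}
    best = min(means, key=means.get)
    flagged = all(
        means[best] < means[o] and pvals[(best, o)] < alpha
        for o in names
        if o != best
    ) if len(names) > 1 else False
    out.attrs["lowest_mean_method"] = best
    out.attrs["flagged"] = flagged
    out["flagged"] = [
        flagged and best in (a, b) and means[best] == min(means[a], means[b])
        for a, b in zip(out["method_a"], out["method_b"])
    ]
    return out
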