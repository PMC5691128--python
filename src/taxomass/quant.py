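"""Taxon-level label-free quantification of proteinaceous biomass.

Signal (PSM counts or precursor intensities) is summed per taxon over
*inferred protein groups*, never over raw peptide matches: shared peptides
are first resolved to a single accepted group by razor assignment, and each
group contributes to the taxon shared by its members.  Groups whose members
span several taxa at the working rank are reported under an explicit
"ambiguous" row and excluded from the fractions by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .inference import ProteinGroup, StrategyResult
from .psm_io import CalibrationRecord
from .seqdb import TaxonomyTree

logger = logging.getLogger(__name__)

QUANT_METHODS = ("psm_count", "unique_intensity", "razor_unique_intensity")

#: pseudo-taxon for accepted groups spanning several taxa at the working rank
AMBIGUOUS = "(ambiguous)"


@dataclass
class TaxonAbundanceTable:
    """Per-taxon raw sums and fractions for one quantification method.

    ``df`` has columns taxon_id, raw, fraction (and corrected_fraction after
    incompleteness correction).  Fractions are normalized over unambiguous
    taxa and sum to 1.
    """

    method: str
    rank: Optional[str]
    df: pd.DataFrame
    ambiguous_raw: float = 0.0
    unassigned_psms: int = 0
    unassigned_fraction: Optional[float] = None
    corrected: bool = False
    provenance: dict = field(default_factory=dict)

    def fractions(self) -> dict[str, float]:
        return dict(zip(self.df["taxon_id"], self.df["fraction"]))

    def corrected_fractions(self) -> dict[str, float]:
        if not self.corrected:
            raise ValueError("table has not been incompleteness-corrected")
        return dict(zip(self.df["taxon_id"], self.df["corrected_fraction"]))

    def raw(self) -> dict[str, float]:
        return dict(zip(self.df["taxon_id"], self.df["raw"]))

    def to_tsv(self, path: str | Path, tree: Optional[TaxonomyTree] = None) -> None:
        out = self.df.copy()
        out.insert(1, "name", out["taxon_id"].map(tree.name_of) if tree else out["taxon_id"])
        out.insert(2, "rank", self.rank or "leaf")
        extra_rows = [
            {"taxon_id": AMBIGUOUS, "name": AMBIGUOUS, "rank": self.rank or "leaf",
             "raw": self.ambiguous_raw, "fraction": np.nan}
        ]
        if self.unassigned_fraction is not None:
            extra_rows.append(
                {"taxon_id": "(unassigned)", "name": "(unassigned)",
                 "rank": self.rank or "leaf", "raw": np.nan,
                 "corrected_fraction": self.unassigned_fraction}
            )
        out = pd.concat([out, pd.DataFrame(extra_rows)], ignore_index=True)
        with open(path, "w") as fh:
            for key, val in self.provenance.items():
                fh.write(f"# {key}: {val}\n")
            fh.write(f"# method: {self.method}\n")
            out.to_csv(fh, sep="\t", index=False)


def _group_taxon(
    group: ProteinGroup, tree: Optional[TaxonomyTree], rank: Optional[str]
) -> str:
    taxa = group.taxon_ids
    if rank is not None and tree is not None:
        taxa = {tree.ancestor_at_rank(t, rank) for t in taxa}
    if len(taxa) == 1:
        return next(iter(taxa))
    return AMBIGUOUS


def assign_razor(
    accepted_groups: list[ProteinGroup],
    group_scores: Optional[Mapping[str, float]] = None,
) -> dict[str, str]:
    """Razor assignment: each peptide of an accepted group goes wholly to the
    accepted group with the most identified peptides (ties: larger summed PSM
    score, then lexicographic group id)."""
    scores = group_scores or {}
    order = sorted(
        accepted_groups,
        key=lambda g: (-len(g.peptides), -scores.get(g.group_id, 0.0), g.group_id),
    )
    assignment: dict[str, str] = {}
    for g in order:
        for pep in g.peptides:
            assignment.setdefault(pep, g.group_id)
    return assignment


def group_psm_counts(
    accepted_psms: pd.DataFrame, razor_map: Mapping[str, str]
) -> dict[str, int]:
    """Number of accepted PSMs razor-assigned to each group."""
    assigned = accepted_psms["peptide"].map(razor_map)
    return assigned.dropna().value_counts().to_dict()


def quantify_taxa(
    accepted_psms: pd.DataFrame,
    strategy_result: StrategyResult,
    groups: list[ProteinGroup],
    method: str = "psm_count",
    tree: Optional[TaxonomyTree] = None,
    rank: Optional[str] = None,
    group_scores: Optional[Mapping[str, float]] = None,
    run_ids: Optional[Iterable[str]] = None,
) -> TaxonAbundanceTable:
    """Sum accepted-PSM signal per taxon for one label-free method.

    ``psm_count``
        each accepted PSM whose peptide is razor-assigned contributes one
        count to the assigned group's taxon.
    ``unique_intensity``
        precursor intensities of PSMs whose peptide maps to exactly one
        accepted group.
    ``razor_unique_intensity``
        precursor intensities summed over the razor assignment.
    """
    if method not in QUANT_METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {QUANT_METHODS}")
    accepted = {g.group_id: g for g in groups if g.group_id in strategy_result.accepted}
    accepted_list = list(accepted.values())
    razor = assign_razor(accepted_list, group_scores)

    if method in ("unique_intensity", "razor_unique_intensity"):
        if accepted_psms["intensity"].isna().all():
            raise ValueError(f"method {method!r} requires precursor intensities")

    if method == "unique_intensity":
        pep_multiplicity = pd.Series(
            [p for g in accepted_list for p in g.peptides], dtype=object
        ).value_counts()
        unique_peps = set(pep_multiplicity[pep_multiplicity == 1].index)
        mask = accepted_psms["peptide"].isin(unique_peps)
        assigned_group = accepted_psms.loc[mask, "peptide"].map(razor)
        weight = accepted_psms.loc[mask, "intensity"].fillna(0.0)
    else:
        assigned_group = accepted_psms["peptide"].map(razor)
        mask = assigned_group.notna()
        assigned_group = assigned_group[mask]
        weight = (
            pd.Series(1.0, index=assigned_group.index)
            if method == "psm_count"
            else accepted_psms.loc[mask, "intensity"].fillna(0.0)
        )

    n_unassigned = int(len(accepted_psms) - mask.sum())
    taxon_of_group = {gid: _group_taxon(g, tree, rank) for gid, g in accepted.items()}
    taxon = assigned_group.map(taxon_of_group)
    sums = weight.groupby(taxon.to_numpy()).sum() if len(taxon) else pd.Series(dtype=float)
    ambiguous_raw = float(sums.get(AMBIGUOUS, 0.0))
    sums = sums.drop(index=AMBIGUOUS, errors="ignore")
    total = float(sums.sum())
    df = pd.DataFrame(
        {
            "taxon_id": sums.index,
            "raw": sums.to_numpy(dtype=float),
            "fraction": sums.to_numpy(dtype=float) / total if total > 0 else 0.0,
        }
    ).sort_values("raw", ascending=False, kind="mergesort").reset_index(drop=True)
    return TaxonAbundanceTable(
        method=method,
        rank=rank,
        df=df,
        ambiguous_raw=ambiguous_raw,
        unassigned_psms=n_unassigned,
        provenance={
            "strategy": strategy_result.strategy,
            "runs": ",".join(sorted(set(run_ids or accepted_psms["run_id"].unique()))),
        },
    )


def aggregate_to_rank(
    table: TaxonAbundanceTable, rank: str, tree: TaxonomyTree
) -> TaxonAbundanceTable:
    """Sum raw signal along ancestor paths to a coarser rank and renormalize."""
    mapped = table.df["taxon_id"].map(lambda t: tree.ancestor_at_rank(t, rank))
    sums = table.df["raw"].groupby(mapped.to_numpy()).sum()
    total = float(sums.sum())
    df = pd.DataFrame(
        {
            "taxon_id": sums.index,
            "raw": sums.to_numpy(dtype=float),
            "fraction": sums.to_numpy(dtype=float) / total if total > 0 else 0.0,
        }
    ).sort_values("raw", ascending=False, kind="mergesort").reset_index(drop=True)
    return replace(table, rank=rank, df=df)


def correct_incompleteness(
    table: TaxonAbundanceTable,
    total_ms2: int,
    calibration: CalibrationRecord,
) -> TaxonAbundanceTable:
    """Correct PSM-count fractions for protein-database incompleteness.

    The expected PSM yield of a complete database is ``calibration.rate *
    total_ms2``; dividing each taxon's observed PSM count by that expectation
    approximates its absolute proteinaceous biomass fraction, with the
    shortfall reported as an explicit unassigned fraction.
    """
    if table.method != "psm_count":
        raise ValueError("incompleteness correction applies to psm_count tables only")
    expected = calibration.rate * total_ms2
    if expected <= 0:
        raise ValueError("calibration yields a zero expected PSM count")
    df = table.df.copy()
    corrected = df["raw"].to_numpy(dtype=float) / expected
    total = corrected.sum()
    if total > 1.0:
        logger.warning(
            "observed PSMs exceed the calibrated expectation (%.0f > %.0f); "
            "corrected fractions renormalized",
            df["raw"].sum(),
            expected,
        )
        corrected = corrected / total
        unassigned = 0.0
    else:
        unassigned = 1.0 - total
    df["corrected_fraction"] = corrected
    prov = dict(table.provenance)
    prov["note"] = "approximation of absolute proteinaceous biomass abundances"
    prov["calibration_rate"] = calibration.rate
    return replace(
        table,
        df=df,
        corrected=True,
        unassigned_fraction=float(unassigned),
        provenance=prov,
    )
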