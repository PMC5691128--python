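"""PSM table ingestion, target-decoy FDR control, and MS2->PSM calibration.

PSM tables are held as pandas DataFrames with a fixed schema
(:data:`PSM_COLUMNS`).  Scores are oriented so that higher is better; decoy
status is derived from the peptide index (a PSM is a decoy hit iff every
protein its peptide maps to is a decoy — peptides shared between targets and
decoys count as target hits, the standard competition convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .seqdb import PeptideIndex, canonicalize

logger = logging.getLogger(__name__)

PSM_COLUMNS = ["spectrum_id", "run_id", "peptide", "engine", "score", "intensity", "is_decoy"]

#: default TSV column names; remap with the ``dialect`` argument
DEFAULT_DIALECT = {
    "spectrum_id": "spectrum_id",
    "run_id": "run_id",
    "peptide": "peptide",
    "score": "score",
    "intensity": "intensity",
    "engine": "engine",
}

_REQUIRED = ("spectrum_id", "run_id", "peptide", "score")


@dataclass(frozen=True)
class PSMRecord:
    """One scored spectrum->peptide match (row view of the PSM table)."""

    spectrum_id: str
    run_id: str
    peptide: str
    engine: str
    score: float
    intensity: Optional[float]
    is_decoy: bool


@dataclass(frozen=True)
class CalibrationRecord:
    """MS2-spectra-to-accepted-PSM yield of a complete-database search.

    The rate is the fraction of acquired MS2 spectra that produced a PSM
    retained for quantification; it anchors the database-incompleteness
    correction.
    """

    total_ms2: int
    accepted_psms: int

    @property
    def rate(self) -> float:
        return self.accepted_psms / self.total_ms2


def compute_calibration(total_ms2: int, accepted_psm_count: int) -> CalibrationRecord:
    if total_ms2 <= 0:
        raise ValueError("total_ms2 must be positive")
    if accepted_psm_count < 0 or accepted_psm_count > total_ms2:
        raise ValueError("accepted PSM count must lie in [0, total_ms2]")
    return CalibrationRecord(total_ms2, accepted_psm_count)


def read_psm_table(
    path: str | Path,
    index: PeptideIndex,
    dialect: Optional[Mapping[str, str]] = None,
    default_engine: str = "A",
) -> pd.DataFrame:
    """Read a PSM TSV, canonicalize peptides and derive decoy status.

    Rows whose peptide is absent from the index are dropped (their count is
    logged and stored in ``df.attrs['n_unindexed_dropped']``).  Only the
    best-scoring record per (spectrum_id, run_id, engine) is kept.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", comment="#")
    for key in _REQUIRED:
        if cols[key] not in df.columns:
            raise ValueError(f"PSM table is missing required column {cols[key]!r}")
    out = pd.DataFrame(
        {
            "spectrum_id": df[cols["spectrum_id"]].astype(str),
            "run_id": df[cols["run_id"]].astype(str),
            "peptide": df[cols["peptide"]].astype(str).map(canonicalize),
            "engine": df[cols["engine"]].astype(str)
            if cols["engine"] in df.columns
            else default_engine,
            "score": df[cols["score"]].astype(float),
            "intensity": df[cols["intensity"]].astype(float)
            if cols["intensity"] in df.columns
            else np.nan,
        }
    )
    return _finalize_psm_frame(out, index)


def _finalize_psm_frame(out: pd.DataFrame, index: PeptideIndex) -> pd.DataFrame:
    if (out["intensity"].dropna() < 0).any():
        raise ValueError("negative intensities in PSM table")
    uniq = out["peptide"].unique()
    indexed = {p for p in uniq if p in index}
    mask = out["peptide"].isin(indexed)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("dropped %d PSM(s) with peptides absent from the index", n_dropped)
    out = out[mask].copy()
    decoy_by_pep = {p: index.decoy_only(p) for p in indexed}
    out["is_decoy"] = out["peptide"].map(decoy_by_pep).astype(bool)
    # rank-1 filter: best score per spectrum within each run and engine
    out = (
        out.sort_values("score", ascending=False, kind="mergesort")
        .drop_duplicates(["spectrum_id", "run_id", "engine"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    out = out[PSM_COLUMNS]
    out.attrs["n_unindexed_dropped"] = n_dropped
    return out


def psm_frame_from_arrays(
    index: PeptideIndex,
    spectrum_id,
    run_id,
    peptide,
    score,
    intensity=None,
    engine: str = "A",
) -> pd.DataFrame:
    """Build a schema-conforming PSM frame from in-memory arrays
    (canonicalization, index filtering and decoy flags applied as in
    :func:`read_psm_table`)."""
    out = pd.DataFrame(
        {
            "spectrum_id": np.asarray(spectrum_id, dtype=object),
            "run_id": run_id,
            "peptide": [canonicalize(p) for p in peptide],
            "engine": engine,
            "score": np.asarray(score, dtype=float),
            "intensity": np.nan if intensity is None else np.asarray(intensity, dtype=float),
        }
    )
    return _finalize_psm_frame(out, index)


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False, columns=PSM_COLUMNS)


# ---------------------------------------------------------------------------
# target-decoy FDR


def target_decoy_qvalues(scores, is_decoy) -> np.ndarray:
    """q-values from target-decoy competition.

    Entries are ranked by descending score (decoys before targets at ties —
    the conservative choice); at each depth FDR = #decoys / max(1, #targets),
    and q-values are the running minimum of FDR from the bottom of the list.
    Returned in the input order.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape:
        raise ValueError("scores and is_decoy must have the same length")
    # lexsort: primary descending score, secondary decoys first
    order = np.lexsort((np.where(is_decoy, 0, 1), -scores))
    d = is_decoy[order]
    cum_decoys = np.cumsum(d)
    cum_targets = np.cumsum(~d)
    fdr = cum_decoys / np.maximum(1, cum_targets)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def psm_fdr_filter(
    psms: pd.DataFrame, fdr_threshold: float = 0.01
) -> tuple[pd.DataFrame, Optional[float]]:
    """Accept target PSMs with q-value <= *fdr_threshold*.

    Returns the accepted PSMs (with a ``q_value`` column; decoys never
    appear) and the score cutoff (lowest accepted score; None if nothing is
    accepted).
    """
    if not 0 < fdr_threshold < 1 and fdr_threshold != 1.0:
        raise ValueError("fdr_threshold must lie in (0, 1]")
    if len(psms) == 0 or not (~psms["is_decoy"]).any():
        logger.warning("PSM set contains no target PSMs; nothing accepted")
        empty = psms.iloc[0:0].copy()
        empty["q_value"] = pd.Series(dtype=float)
        return empty, None
    q = target_decoy_qvalues(psms["score"].to_numpy(), psms["is_decoy"].to_numpy())
    accepted = psms[(q <= fdr_threshold) & (~psms["is_decoy"])].copy()
    accepted["q_value"] = q[(q <= fdr_threshold) & (~psms["is_decoy"].to_numpy())]
    cutoff = float(accepted["score"].min()) if len(accepted) else None
    return accepted.reset_index(drop=True), cutoff
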