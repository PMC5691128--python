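"""End-to-end orchestration: index -> ingest -> infer -> quantify -> correct.

``run_pipeline`` is the in-memory composition used by tests, benchmarks and
the CLI; ``run_profile`` wraps it with file IO, config validation and
provenance capture.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .inference import (
    DEFAULT_STRATEGY,
    FidoParams,
    ProteinGroup,
    StrategyResult,
    apply_inference_strategy,
    group_proteins,
    infer,
    write_inference_report,
)
from .psm_io import CalibrationRecord, psm_fdr_filter, read_psm_table
from .quant import (
    TaxonAbundanceTable,
    correct_incompleteness,
    group_psm_counts,
    assign_razor,
    quantify_taxa,
)
from .seqdb import (
    DigestParams,
    PeptideIndex,
    ProteinRecord,
    TaxonomyTree,
    build_peptide_index,
    generate_decoys,
    read_fasta,
    read_taxonomy_map,
    remove_exact_duplicates,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    db_fasta: str
    taxonomy_map: str
    taxonomy_tree: str
    psm_tables: list[str]
    output_dir: str
    truth: Optional[str] = None
    digest: DigestParams = field(default_factory=DigestParams)
    psm_fdr: float = 0.01
    strategy: str = DEFAULT_STRATEGY
    fido: FidoParams = field(default_factory=FidoParams)
    method: str = "psm_count"
    rank: Optional[str] = None
    total_ms2: Optional[int] = None
    calibration_rate: Optional[float] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        digest = DigestParams(**raw.pop("digest", {}))
        fido = FidoParams(**raw.pop("fido", {}))
        return cls(digest=digest, fido=fido, **raw)

    def validate(self) -> None:
        for path in [self.db_fasta, self.taxonomy_map, self.taxonomy_tree, *self.psm_tables]:
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")
        if not 0 < self.psm_fdr < 1:
            raise ValueError("psm_fdr must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where outputs land is not provenance
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    index: PeptideIndex
    accepted_psms: pd.DataFrame
    groups: list[ProteinGroup]
    inference_table: pd.DataFrame
    strategy_result: StrategyResult
    abundance: TaxonAbundanceTable
    corrected: Optional[TaxonAbundanceTable] = None

    def group_taxa(self, tree: Optional[TaxonomyTree] = None, rank: Optional[str] = None):
        from .quant import _group_taxon

        return {
            g.group_id: _group_taxon(g, tree, rank)
            for g in self.groups
            if g.group_id in self.strategy_result.accepted
        }

    def assigned_group_counts(self) -> dict[str, int]:
        accepted = [g for g in self.groups if g.group_id in self.strategy_result.accepted]
        scores = dict(
            zip(self.inference_table["group_id"], self.inference_table["score_a"])
        )
        return group_psm_counts(self.accepted_psms, assign_razor(accepted, scores))


def run_pipeline(
    db: list[ProteinRecord],
    tree: Optional[TaxonomyTree],
    psms: pd.DataFrame,
    *,
    index: Optional[PeptideIndex] = None,
    digest: DigestParams = DigestParams(),
    psm_fdr: float = 0.01,
    strategy: str = DEFAULT_STRATEGY,
    fido: FidoParams = FidoParams(),
    method: str = "psm_count",
    rank: Optional[str] = None,
    taxon_map: Optional[Mapping[str, str]] = None,
    calibration: Optional[CalibrationRecord] = None,
    total_ms2: Optional[int] = None,
    psms_prefiltered: bool = False,
) -> PipelineResult:
    """Run inference and quantification on an already-loaded database and
    PSM frame.  *db* must contain decoys (see :func:`generate_decoys`)."""
    if index is None:
        index = build_peptide_index(db, digest)
    if taxon_map is None:
        taxon_map = {p.accession: p.taxon_id for p in db if not p.is_decoy}
    if psms_prefiltered:
        accepted = psms
    else:
        accepted, _ = psm_fdr_filter(psms, psm_fdr)
    groups = group_proteins(accepted["peptide"].unique(), index, taxon_map)
    table = infer(groups, accepted, index, fido)
    result = apply_inference_strategy(strategy, table)
    scores = dict(zip(table["group_id"], table["score_a"]))
    abundance = quantify_taxa(
        accepted, result, groups, method=method, tree=tree, rank=rank, group_scores=scores
    )
    corrected = None
    if calibration is not None:
        if total_ms2 is None:
            raise ValueError("total_ms2 is required for incompleteness correction")
        corrected = correct_incompleteness(abundance, total_ms2, calibration)
    return PipelineResult(index, accepted, groups, table, result, abundance, corrected)


def run_profile(config: RunConfig) -> PipelineResult:
    """File-based end-to-end profiling run with provenance capture."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    taxonomy = stage("taxonomy", read_taxonomy_map, config.taxonomy_map)
    tree = stage("taxonomy", TaxonomyTree.from_tsv, config.taxonomy_tree)
    targets = stage("read_fasta", read_fasta, config.db_fasta, taxonomy)
    targets, dropped = remove_exact_duplicates(targets)
    if dropped:
        logger.info("collapsed %d exact-duplicate sequence(s)", len(dropped))
    db = targets + generate_decoys(targets)
    index = stage("index", build_peptide_index, db, config.digest)
    frames = [
        stage("read_psms", read_psm_table, path, index) for path in config.psm_tables
    ]
    psms = pd.concat(frames, ignore_index=True)
    calibration = None
    if config.calibration_rate is not None and config.total_ms2 is not None:
        calibration = CalibrationRecord(
            config.total_ms2, int(round(config.calibration_rate * config.total_ms2))
        )
    result = stage(
        "pipeline",
        run_pipeline,
        db,
        tree,
        psms,
        index=index,
        digest=config.digest,
        psm_fdr=config.psm_fdr,
        strategy=config.strategy,
        fido=config.fido,
        method=config.method,
        rank=config.rank,
        taxon_map=taxonomy,
        calibration=calibration,
        total_ms2=config.total_ms2,
    )

    provenance = {
        "tool": f"taxomass {__version__}",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "strategy": config.strategy,
    }
    result.abundance.provenance.update(provenance)
    strategies = [result.strategy_result]
    write_inference_report(
        result.inference_table, strategies, outdir / "inference_report.tsv"
    )
    result.abundance.to_tsv(outdir / "abundance.tsv", tree)
    if result.corrected is not None:
        result.corrected.provenance.update(provenance)
        result.corrected.to_tsv(outdir / "abundance_corrected.tsv", tree)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return result
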