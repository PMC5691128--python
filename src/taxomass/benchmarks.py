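"""Composed benchmark runs on simulated mock communities.

These functions wire the simulator to the inference/quantification pipeline
and the evaluation metrics, mirroring the three validation experiments the
method rests on: strategy specificity vs. sensitivity on pure cultures with
related organisms in the database, recovery of known community composition,
and robustness of incompleteness-corrected abundances when taxa are removed
from the database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .evaluation import (
    CommunityTruth,
    detection_summary,
    deviation_report,
    sensitivity,
    specificity,
)
from .inference import DEFAULT_STRATEGY, STRATEGIES, FidoParams, apply_inference_strategy
from .psm_io import CalibrationRecord, psm_frame_from_arrays
from .quant import quantify_taxa
from .seqdb import build_peptide_index, generate_decoys
from .simulate import (
    CommunitySpec,
    SimulationConfig,
    make_incomplete_db,
    scenario_fig2,
    simulate_community_bundle,
    uneven_community,
)
from .workflow import PipelineResult, run_pipeline


@dataclass
class ScenarioRun:
    """One pure-culture relatedness scenario profiled against the shared
    community database, with every filtering strategy applied."""

    scenario: str
    analyzed_taxon: str
    truth_taxa: frozenset
    pipeline: PipelineResult
    strategy_results: dict  # strategy -> StrategyResult
    tables: dict  # strategy -> TaxonAbundanceTable (psm_count)


def scenario_pipelines(
    config: SimulationConfig,
    strategies: Optional[Iterable[str]] = None,
    psm_fdr: float = 0.05,
) -> dict[str, ScenarioRun]:
    """Profile the four relatedness scenarios (strain / species / genus
    siblings and an unrelated archaeon) against one 30-taxon database and
    apply every filtering strategy to each."""
    strategies = list(strategies or STRATEGIES)
    proteins, tree, taxon_map, bundles = scenario_fig2(config)
    db = proteins + generate_decoys(proteins)
    index = build_peptide_index(db, config.digest)
    runs: dict[str, ScenarioRun] = {}
    for scenario, bundle in bundles.items():
        raw = bundle.psms_raw
        psms = psm_frame_from_arrays(
            index,
            raw["spectrum_id"].to_numpy(),
            raw["run_id"].to_numpy(),
            raw["peptide"].tolist(),
            raw["score"].to_numpy(),
            raw["intensity"].to_numpy(),
        )
        base = run_pipeline(
            db, tree, psms, index=index, taxon_map=taxon_map, psm_fdr=psm_fdr,
            strategy=DEFAULT_STRATEGY,
        )
        scores = dict(zip(base.inference_table["group_id"], base.inference_table["score_a"]))
        results = {}
        tables = {}
        for name in strategies:
            result = apply_inference_strategy(name, base.inference_table)
            results[name] = result
            tables[name] = quantify_taxa(
                base.accepted_psms, result, base.groups,
                method="psm_count", tree=tree, rank=None, group_scores=scores,
            )
        runs[scenario] = ScenarioRun(
            scenario, bundle.analyzed_taxon, bundle.truth_taxa, base, results, tables
        )
    return runs


def scenario_strategy_sweep(
    config: SimulationConfig,
    strategies: Optional[Iterable[str]] = None,
    psm_fdr: float = 0.05,
) -> pd.DataFrame:
    """Specificity and sensitivity of each filtering strategy on the four
    relatedness scenarios.

    Specificity is the fraction of quantified signal attributed to the
    analyzed organism; sensitivity the number of accepted groups for it.
    """
    runs = scenario_pipelines(config, strategies, psm_fdr)
    rows = []
    for scenario, run in runs.items():
        for name, result in run.strategy_results.items():
            rows.append(
                {
                    "scenario": scenario,
                    "analyzed_taxon": run.analyzed_taxon,
                    "strategy": name,
                    "specificity": specificity(run.tables[name], run.truth_taxa),
                    "sensitivity": sensitivity(
                        result, run.pipeline.groups, run.analyzed_taxon
                    ),
                    "n_accepted": len(result.accepted),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CommunityBenchmark:
    spec: CommunitySpec
    truth: CommunityTruth
    pipeline: PipelineResult
    abundances: dict  # method -> TaxonAbundanceTable
    deviations: dict  # method -> per-taxon deviation DataFrame
    n_detected: int
    detection: pd.DataFrame
    total_ms2: int


def community_benchmark(
    spec: CommunitySpec,
    config: SimulationConfig,
    methods: Iterable[str] = ("psm_count", "unique_intensity", "razor_unique_intensity"),
    strategy: str = DEFAULT_STRATEGY,
    psm_fdr: float = 0.01,
    convention: str = "ratio",
    bundle=None,
) -> CommunityBenchmark:
    """Simulate one community, profile it, and compare every quantification
    method's taxon fractions with the known inputs."""
    if bundle is None:
        bundle = simulate_community_bundle(spec, config)
    db, tree, taxon_map, index, psms, total_ms2 = bundle
    pipeline = run_pipeline(
        db, tree, psms, index=index, taxon_map=taxon_map, psm_fdr=psm_fdr,
        strategy=strategy,
    )
    truth = spec.truth()
    scores = dict(
        zip(pipeline.inference_table["group_id"], pipeline.inference_table["score_a"])
    )
    abundances = {}
    deviations = {}
    for method in methods:
        table = quantify_taxa(
            pipeline.accepted_psms, pipeline.strategy_result, pipeline.groups,
            method=method, tree=tree, rank=None, group_scores=scores,
        )
        abundances[method] = table
        deviations[method] = deviation_report(table.fractions(), truth, convention)
    n_detected, detection = detection_summary(
        pipeline.group_taxa(tree, None), pipeline.assigned_group_counts(), truth
    )
    return CommunityBenchmark(
        spec, truth, pipeline, abundances, deviations, n_detected, detection, total_ms2
    )


@dataclass
class IncompletenessBenchmark:
    complete: CommunityBenchmark
    incomplete_pipeline: PipelineResult
    dropped_taxa: frozenset
    uncorrected_fractions: dict
    corrected_fractions: dict
    unassigned_fraction: float
    calibration: CalibrationRecord


def incompleteness_benchmark(
    config: SimulationConfig,
    drop: Iterable[str],
    spec: Optional[CommunitySpec] = None,
    strategy: str = DEFAULT_STRATEGY,
    psm_fdr: float = 0.01,
) -> IncompletenessBenchmark:
    """Quantify one simulated sample against the complete database and
    against a database missing *drop* taxa, then correct the incomplete
    result using the complete run's MS2->quantified-PSM calibration.

    The same simulated acquisition (identical PSM table) is searched against
    both databases, as in a real re-search with a reduced FASTA.
    """
    spec = spec or uneven_community()
    bundle = simulate_community_bundle(spec, config)
    complete = community_benchmark(
        spec, config, methods=("psm_count",), strategy=strategy, psm_fdr=psm_fdr,
        bundle=bundle,
    )
    total_ms2 = complete.total_ms2
    quantified = sum(complete.abundances["psm_count"].raw().values())
    calibration = CalibrationRecord(total_ms2, int(round(quantified)))

    dropped = frozenset(drop)
    db, tree, taxon_map, index, psms, _ = bundle
    sub_db = make_incomplete_db(db, dropped)
    sub_index = build_peptide_index(sub_db, config.digest)
    # re-read the same PSM evidence against the reduced search space
    raw = psms
    sub_psms = psm_frame_from_arrays(
        sub_index,
        raw["spectrum_id"].to_numpy(),
        raw["run_id"].to_numpy(),
        raw["peptide"].tolist(),
        raw["score"].to_numpy(),
        raw["intensity"].to_numpy(),
    )
    sub_map = {a: t for a, t in taxon_map.items() if t not in dropped}
    incomplete = run_pipeline(
        sub_db, tree, sub_psms, index=sub_index, taxon_map=sub_map,
        psm_fdr=psm_fdr, strategy=strategy,
        calibration=calibration, total_ms2=total_ms2,
    )
    return IncompletenessBenchmark(
        complete=complete,
        incomplete_pipeline=incomplete,
        dropped_taxa=dropped,
        uncorrected_fractions=incomplete.abundance.fractions(),
        corrected_fractions=incomplete.corrected.corrected_fractions(),
        unassigned_fraction=incomplete.corrected.unassigned_fraction,
        calibration=calibration,
    )
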