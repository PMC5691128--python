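"""Protein inference: grouping, scoring engines, and filtering strategies.

Peptide-to-protein ambiguity is resolved in three layers:

1. *Grouping* — proteins whose identified-peptide sets are identical are
   merged, and proteins whose sets are strict subsets of another protein's
   set are absorbed (parsimony subsumption).  Groups are the unit everything
   downstream works on.
2. *Scoring* — two independent engines rank groups.  Engine A sums the best
   PSM score per identified peptide and converts ranks to q-values by
   target-decoy competition.  Engine B computes Bayesian posteriors under a
   Fido-style generative model (protein present with prior gamma; a present
   parent emits its peptide with probability alpha; any peptide can arise
   from noise with probability beta) and likewise converts the posterior
   ranking to decoy-calibrated q-values.
3. *Filtering strategies* — seven acceptance rules of increasing stringency
   combine engine thresholds with unique-peptide (UP) and protein-unique-
   peptide (PUP) requirements.  The strategy algebra lives in
   :data:`STRATEGIES`.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .psm_io import target_decoy_qvalues
from .seqdb import DECOY_PREFIX, PeptideIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FidoParams:
    """Hyperparameters of the Bayesian protein-inference engine.

    alpha
        probability that a present protein emits (explains) one of its
        identified peptides.
    beta
        probability that a peptide is observed with no present parent
        (noise floor).
    gamma
        prior presence probability of a protein group.
    max_exact_component
        largest connected component (number of groups) evaluated by exact
        enumeration over presence vectors; larger components are pruned and,
        if necessary, split.
    pruning_floor
        peptide probability below which peptides are discarded when a
        component must be reduced.
    """

    alpha: float = 0.9
    beta: float = 0.01
    gamma: float = 0.3
    max_exact_component: int = 12
    pruning_floor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class ProteinGroup:
    """Proteins indistinguishable (identical or subsumed) by identified
    peptides.

    ``principal`` members carry the group's full identified-peptide set;
    other members were absorbed by parsimony (their evidence is a strict
    subset) and do not define the group's taxonomic attribution.
    """

    group_id: str
    members: tuple[str, ...]
    peptides: frozenset[str]
    leading: str
    taxon_ids: frozenset[str]
    is_decoy: bool
    principal: tuple[str, ...] = ()


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    accepted: frozenset[str]  # group_ids; decoy groups never appear
    thresholds: Mapping[str, float]


# ---------------------------------------------------------------------------
# grouping


def group_proteins(
    identified_peptides: Iterable[str],
    index: PeptideIndex,
    taxon_map: Optional[Mapping[str, str]] = None,
) -> list[ProteinGroup]:
    """Group proteins by their identified-peptide sets.

    Proteins with identical sets merge into one group; a protein whose set is
    a strict subset of another's is absorbed into that protein's group (when
    several supersets exist, the largest wins, ties broken by smallest
    leading accession).  Only identified peptides participate — the
    theoretical digest plays no role here.
    """
    identified = set(identified_peptides)
    prot_peps: dict[str, set[str]] = defaultdict(set)
    for pep in identified:
        for acc in index.accessions_for(pep):
            prot_peps[acc].add(pep)

    by_set: dict[frozenset[str], list[str]] = defaultdict(list)
    for acc, peps in prot_peps.items():
        by_set[frozenset(peps)].append(acc)

    sets = list(by_set)
    set_leading = {s: min(by_set[s]) for s in sets}
    postings: dict[str, list[frozenset[str]]] = defaultdict(list)
    for s in sets:
        for pep in s:
            postings[pep].append(s)

    absorbed_into: dict[frozenset[str], frozenset[str]] = {}
    for s in sets:
        # candidate supersets contain every peptide of s
        peps = sorted(s, key=lambda p: len(postings[p]))
        cands = set(postings[peps[0]])
        for pep in peps[1:]:
            cands &= set(postings[pep])
            if len(cands) <= 1:
                break
        cands.discard(s)
        if cands:
            target = min(cands, key=lambda t: (-len(t), set_leading[t]))
            absorbed_into[s] = target

    groups: list[ProteinGroup] = []
    for s in sets:
        if s in absorbed_into:
            continue
        principal = tuple(sorted(by_set[s]))
        members = list(principal)
        # pull in every set (transitively) absorbed by this one
        for src, dst in absorbed_into.items():
            root = dst
            while root in absorbed_into:
                root = absorbed_into[root]
            if root == s:
                members.extend(by_set[src])
        members = tuple(sorted(members))
        leading = principal[0]
        target_principal = [m for m in principal if not m.startswith(DECOY_PREFIX)]
        is_decoy = not any(not m.startswith(DECOY_PREFIX) for m in members)
        # taxonomic attribution follows the principal members: absorbed
        # subset members do not widen the group's taxon set
        taxa = frozenset(
            taxon_map[m]
            for m in (target_principal or principal)
            if taxon_map and m in taxon_map
        )
        groups.append(
            ProteinGroup(leading, members, s, leading, taxa, is_decoy, principal)
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def count_unique_peptides(group: ProteinGroup, groups: Iterable[ProteinGroup]) -> int:
    """Identified peptides mapping to members of *group* only."""
    return unique_peptide_counts(list(groups)).get(group.group_id, 0)


def unique_peptide_counts(groups: list[ProteinGroup]) -> dict[str, int]:
    pep_multiplicity: Counter[str] = Counter()
    for g in groups:
        pep_multiplicity.update(g.peptides)
    return {
        g.group_id: sum(1 for p in g.peptides if pep_multiplicity[p] == 1)
        for g in groups
    }


def count_protein_unique_peptides(
    group: ProteinGroup, index: PeptideIndex
) -> int:
    """Identified peptides of the group mapping to exactly one protein
    sequence in the whole database (targets + decoys)."""
    return sum(1 for p in g_peps(group) if index.is_protein_unique(p))


def g_peps(group: ProteinGroup) -> frozenset[str]:
    return group.peptides


def protein_unique_peptide_counts(
    groups: list[ProteinGroup], index: PeptideIndex
) -> dict[str, int]:
    return {g.group_id: count_protein_unique_peptides(g, index) for g in groups}


# ---------------------------------------------------------------------------
# engine A: additive score + target-decoy q-values


def score_protein_groups_engineA(
    groups: list[ProteinGroup], accepted_psms: pd.DataFrame
) -> pd.DataFrame:
    """Score groups as the sum of the best PSM score per identified peptide
    and derive target-decoy q-values over the group ranking."""
    best = accepted_psms.groupby("peptide")["score"].max()
    n_psms = accepted_psms["peptide"].value_counts()
    rows = []
    for g in groups:
        peps = [p for p in g.peptides if p in best.index]
        score = float(best.loc[peps].sum()) if peps else 0.0
        count = int(n_psms.loc[peps].sum()) if peps else 0
        rows.append((g.group_id, score, count, g.is_decoy))
    df = pd.DataFrame(rows, columns=["group_id", "score_a", "psm_count", "is_decoy"])
    df["q_a"] = target_decoy_qvalues(df["score_a"].to_numpy(), df["is_decoy"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# engine B: Fido-style Bayesian posteriors


def peptide_probabilities(
    psms: pd.DataFrame, floor: float = 0.01, cap: float = 0.99
) -> dict[str, float]:
    """Monotone score -> probability transform feeding the Bayesian engine.

    PSM scores are standardized within each run and passed through a
    logistic; each peptide takes the maximum over its PSMs, clipped to
    [floor, cap].
    """
    if len(psms) == 0:
        return {}
    z = psms.groupby("run_id")["score"].transform(
        lambda s: (s - s.mean()) / (s.std(ddof=0) or 1.0)
    )
    p = 1.0 / (1.0 + np.exp(-z.to_numpy()))
    p = np.clip(p, floor, cap)
    return (
        pd.Series(p, index=psms["peptide"].to_numpy()).groupby(level=0).max().to_dict()
    )


def _exact_component_posteriors(
    k: int,
    membership: np.ndarray,  # (n_pep, k) bool: peptide j belongs to group i
    probs: np.ndarray,  # (n_pep,)
    params: FidoParams,
) -> np.ndarray:
    """Exact posteriors by enumeration over all 2**k presence vectors.

    For a presence vector v the peptide emission probability is
    ``1 - (1-beta) * (1-alpha)**m`` with m the number of present parents.
    A peptide observed with probability p contributes the soft-evidence
    factor ``(1-p) + p * P(emit | v)`` so that p = 0 carries no evidence and
    the posterior collapses to the prior.
    """
    n_vec = 1 << k
    vec = np.arange(n_vec, dtype=np.int64)
    present = ((vec[:, None] >> np.arange(k)) & 1).astype(float)  # (2^k, k)
    m = present @ membership.T.astype(float)  # (2^k, n_pep)
    p_emit = 1.0 - (1.0 - params.beta) * (1.0 - params.alpha) ** m
    lik = np.prod(1.0 - probs[None, :] * (1.0 - p_emit), axis=1)
    n_present = present.sum(axis=1)
    prior = params.gamma**n_present * (1.0 - params.gamma) ** (k - n_present)
    w = lik * prior
    total = w.sum()
    return (present * w[:, None]).sum(axis=0) / total


def _connected_components(
    group_peps: dict[str, list[str]]
) -> list[list[str]]:
    pep_groups: dict[str, list[str]] = defaultdict(list)
    for gid, peps in group_peps.items():
        for p in peps:
            pep_groups[p].append(gid)
    seen: set[str] = set()
    comps = []
    for gid in group_peps:
        if gid in seen:
            continue
        comp = []
        stack = [gid]
        seen.add(gid)
        while stack:
            g = stack.pop()
            comp.append(g)
            for p in group_peps[g]:
                for h in pep_groups[p]:
                    if h not in seen:
                        seen.add(h)
                        stack.append(h)
        comps.append(comp)
    return comps


def fido_posteriors(
    groups: list[ProteinGroup],
    peptide_probs: Mapping[str, float],
    params: FidoParams = FidoParams(),
) -> dict[str, float]:
    """Posterior presence probability per protein group.

    Connected components of the group/peptide bipartite graph with at most
    ``max_exact_component`` groups are solved exactly; larger components are
    reduced by discarding peptides below the pruning floor, dropping groups
    left without evidence (their posterior is the prior), and finally by
    removing the weakest shared peptides until the component splits.
    """
    group_peps = {
        g.group_id: [p for p in g.peptides if p in peptide_probs] for g in groups
    }
    posteriors: dict[str, float] = {}

    def solve(sub: dict[str, list[str]]) -> None:
        for comp in _connected_components(sub):
            if len(comp) <= params.max_exact_component:
                _solve_exact(comp, sub)
            else:
                _reduce(comp, sub)

    def _solve_exact(comp: list[str], sub: dict[str, list[str]]) -> None:
        peps = sorted({p for g in comp for p in sub[g]})
        if not peps:
            for g in comp:
                posteriors[g] = params.gamma
            return
        gidx = {g: i for i, g in enumerate(comp)}
        pidx = {p: j for j, p in enumerate(peps)}
        membership = np.zeros((len(peps), len(comp)), dtype=bool)
        for g in comp:
            for p in sub[g]:
                membership[pidx[p], gidx[g]] = True
        probs = np.array([peptide_probs[p] for p in peps])
        post = _exact_component_posteriors(len(comp), membership, probs, params)
        for g in comp:
            posteriors[g] = float(post[gidx[g]])

    def _reduce(comp: list[str], sub: dict[str, list[str]]) -> None:
        pruned = {
            g: [p for p in sub[g] if peptide_probs[p] >= params.pruning_floor]
            for g in comp
        }
        empty = [g for g in comp if not pruned[g]]
        for g in empty:
            posteriors[g] = params.gamma
            del pruned[g]
        if not pruned:
            return
        comps = _connected_components(pruned)
        if all(len(c) <= params.max_exact_component for c in comps):
            solve(pruned)
            return
        # remove the weakest shared peptides (lowest degree, then lowest
        # probability) until every component is tractable
        degree: Counter[str] = Counter()
        for peps in pruned.values():
            degree.update(peps)
        shared = sorted(
            (p for p, d in degree.items() if d >= 2),
            key=lambda p: (degree[p], peptide_probs[p]),
        )
        removed: set[str] = set()
        for p in shared:
            removed.add(p)
            trimmed = {g: [q for q in peps if q not in removed] for g, peps in pruned.items()}
            comps = _connected_components(trimmed)
            if all(len(c) <= params.max_exact_component for c in comps):
                logger.warning(
                    "component of %d groups split by removing %d shared peptide(s)",
                    len(comp),
                    len(removed),
                )
                solve(trimmed)
                return
        # every shared peptide removed: components are singletons
        trimmed = {g: [q for q in peps if q not in removed] for g, peps in pruned.items()}
        logger.warning(
            "component of %d groups irreducible; solved with all shared peptides removed",
            len(comp),
        )
        solve(trimmed)

    solve(group_peps)
    return posteriors


def score_protein_groups_engineB(
    groups: list[ProteinGroup],
    accepted_psms: pd.DataFrame,
    params: FidoParams = FidoParams(),
) -> pd.DataFrame:
    """Fido posteriors plus decoy-calibrated q-values over the posterior
    ranking."""
    probs = peptide_probabilities(accepted_psms)
    post = fido_posteriors(groups, probs, params)
    df = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "posterior": [post.get(g.group_id, params.gamma) for g in groups],
            "is_decoy": [g.is_decoy for g in groups],
        }
    )
    df["q_b"] = target_decoy_qvalues(df["posterior"].to_numpy(), df["is_decoy"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# combined inference table and strategies


def infer(
    groups: list[ProteinGroup],
    accepted_psms: pd.DataFrame,
    index: PeptideIndex,
    fido_params: FidoParams = FidoParams(),
) -> pd.DataFrame:
    """Run both engines and assemble the per-group inference table."""
    a = score_protein_groups_engineA(groups, accepted_psms)
    b = score_protein_groups_engineB(groups, accepted_psms, fido_params)
    up = unique_peptide_counts(groups)
    pup = protein_unique_peptide_counts(groups, index)
    table = a.merge(b.drop(columns="is_decoy"), on="group_id")
    table["n_up"] = table["group_id"].map(up)
    table["n_pup"] = table["group_id"].map(pup)
    table["members"] = table["group_id"].map(
        {g.group_id: ";".join(g.members) for g in groups}
    )
    table["taxon_ids"] = table["group_id"].map(
        {g.group_id: ";".join(sorted(g.taxon_ids)) for g in groups}
    )
    return table


def _b2_clause(t: pd.DataFrame) -> pd.Series:
    # second-engine stand-in: engine A at 1% FDR with >= 2 unique peptides
    return (t["q_a"] <= 0.01) & (t["n_up"] >= 2)


STRATEGIES: dict[str, callable] = {
    "SQ_5FDR": lambda t: t["q_a"] <= 0.05,
    "2UP": lambda t: (t["q_a"] <= 0.05) & (t["n_up"] >= 2),
    "FIDO_5FDR": lambda t: t["q_b"] <= 0.05,
    "2PUP_FIDO": lambda t: (t["q_b"] <= 0.05) & (t["n_pup"] >= 2),
    "FIDO_AND_B2": lambda t: (t["q_b"] <= 0.05) & _b2_clause(t),
    "2PUP_FIDO_AND_B2": lambda t: (t["q_b"] <= 0.05) & (t["n_pup"] >= 2) & _b2_clause(t),
    "FIDO_AND_B2_OR_3PUP": lambda t: (t["q_b"] <= 0.05)
    & (_b2_clause(t) | (t["n_pup"] >= 3)),
}

#: default acceptance rule: Bayesian engine at 5% FDR plus two
#: protein-unique peptides
DEFAULT_STRATEGY = "2PUP_FIDO"

_THRESHOLDS: dict[str, dict[str, float]] = {
    "SQ_5FDR": {"q_a": 0.05},
    "2UP": {"q_a": 0.05, "n_up": 2},
    "FIDO_5FDR": {"q_b": 0.05},
    "2PUP_FIDO": {"q_b": 0.05, "n_pup": 2},
    "FIDO_AND_B2": {"q_b": 0.05, "q_a": 0.01, "n_up": 2},
    "2PUP_FIDO_AND_B2": {"q_b": 0.05, "n_pup": 2, "q_a": 0.01, "n_up": 2},
    "FIDO_AND_B2_OR_3PUP": {"q_b": 0.05, "q_a": 0.01, "n_up": 2, "n_pup": 3},
}


def apply_inference_strategy(name: str, table: pd.DataFrame) -> StrategyResult:
    """Apply one of the seven acceptance rules to an inference table."""
    if name not in STRATEGIES:
        raise ValueError(
            f"unknown strategy {name!r}; valid strategies: {sorted(STRATEGIES)}"
        )
    mask = STRATEGIES[name](table) & (~table["is_decoy"])
    return StrategyResult(
        name, frozenset(table.loc[mask, "group_id"]), _THRESHOLDS[name]
    )


def write_inference_report(
    table: pd.DataFrame,
    results: Iterable[StrategyResult],
    path: str | Path,
) -> None:
    """Inference table TSV with one boolean acceptance column per strategy."""
    out = table.copy()
    for res in results:
        out[f"accepted_{res.strategy}"] = out["group_id"].isin(res.accepted)
    cols = [
        "group_id",
        "members",
        "taxon_ids",
        "is_decoy",
        "score_a",
        "q_a",
        "posterior",
        "q_b",
        "n_up",
        "n_pup",
        "psm_count",
    ] + [c for c in out.columns if c.startswith("accepted_")]
    out.to_csv(path, sep="\t", index=False, columns=cols)
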