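"""Mock-community and synthetic LC-MS/MS identification data generator.

The generator emulates the benchmark design used to validate taxon-level
biomass profiling: defined communities of bacteria (including near-identical
strain pairs and related species/genus groups), an archaeon, a eukaryotic
alga and several bacteriophages, mixed at known protein fractions, digested
and acquired on a simulated instrument with a configurable MS2-spectra
budget.

Sequence relatedness is simulated mechanistically: members of a relatedness
group are derived from a shared ancestral proteome by i.i.d. point
substitutions calibrated to a pairwise identity target, so peptide sharing —
and with it the protein inference problem — emerges from digestion exactly
as in real data rather than being declared.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``; identical configurations produce byte-identical
FASTA and PSM outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .evaluation import CommunityTruth
from .psm_io import psm_frame_from_arrays
from .seqdb import (
    DigestParams,
    PeptideIndex,
    ProteinRecord,
    TaxonNode,
    TaxonomyTree,
    build_peptide_index,
    canonicalize,
    count_missed_cleavages,
    digest,
    generate_decoys,
)

ORGANISM_CLASSES = ("gram_neg", "gram_pos", "archaeon", "eukaryote", "phage")
RELATEDNESS_LEVELS = ("strain", "species", "genus")

# approximate background amino-acid frequencies (no X); K+R ~ 11% so the
# mean fully-tryptic peptide is ~9 residues long
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [0.082, 0.014, 0.054, 0.067, 0.039, 0.071, 0.022, 0.060, 0.058, 0.096,
     0.024, 0.044, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.029]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: rough per-cell protein mass by organism class, relative to a gram-negative
#: bacterium (eukaryotic algae carry orders of magnitude more protein per
#: cell; phage particles almost none)
CELL_PROTEIN_MASS = {
    "gram_neg": 1.0,
    "gram_pos": 1.2,
    "archaeon": 0.7,
    "eukaryote": 3000.0,
    "phage": 0.005,
}


@dataclass(frozen=True)
class CommunityMember:
    taxon_id: str
    organism_class: str
    input_protein_fraction: float
    input_cell_fraction: float
    relatedness_group: Optional[str] = None
    relatedness_level: Optional[str] = None


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth design of a mock community."""

    community_type: str  # uneven | equal_protein | equal_cell | custom
    members: tuple[CommunityMember, ...]

    def __post_init__(self) -> None:
        total = sum(m.input_protein_fraction for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"protein fractions must sum to 1, got {total:.12f}")
        if self.community_type == "uneven":
            fracs = [m.input_protein_fraction for m in self.members if m.input_protein_fraction > 0]
            if max(fracs) / min(fracs) < 100:
                raise ValueError("uneven community must span >= 2 orders of magnitude")
            bact = [
                m.input_protein_fraction
                for m in self.members
                if m.organism_class in ("gram_neg", "gram_pos")
            ]
            if min(bact) < 0.0008 - 1e-12:
                raise ValueError("minimum bacterial protein fraction is 0.0008")

    def truth(self) -> CommunityTruth:
        df = pd.DataFrame(
            {
                "taxon_id": [m.taxon_id for m in self.members],
                "input_protein_fraction": [m.input_protein_fraction for m in self.members],
                "input_cell_fraction": [m.input_cell_fraction for m in self.members],
            }
        )
        return CommunityTruth(df)


@dataclass(frozen=True)
class SimulationConfig:
    """Stochastic generation parameters for proteomes and PSM data."""

    seed: int = 0
    n_proteins: dict = field(
        default_factory=lambda: {
            "gram_neg": 80,
            "gram_pos": 80,
            "archaeon": 60,
            "eukaryote": 160,
            "phage": 8,
        }
    )
    protein_length_log_mean: float = math.log(280.0)
    protein_length_log_sigma: float = 0.35
    min_protein_length: int = 60
    identity_targets: dict = field(
        default_factory=lambda: {"strain": 0.99, "species": 0.95, "genus": 0.85}
    )
    n_ms2: int = 130_000  # one long 1D-LC-MS/MS run's worth of MS2 spectra
    id_rate: float = 0.4  # fraction of spectra yielding a correct PSM
    noise_rate: float = 0.15  # fraction of the remaining spectra yielding a false match
    # data-dependent acquisition only triggers MS2 on sufficiently intense
    # precursors: a candidate identification of a protein with relative
    # abundance w succeeds with probability w / (w + lod_weight), so
    # proteins near the detection limit are undersampled non-linearly
    lod_weight: float = 1e-5
    abundance_sigma: float = 1.2  # within-taxon log-normal protein abundance spread
    target_score_mu: float = 3.5
    target_score_sigma: float = 1.0
    null_score_mu: float = 0.0
    null_score_sigma: float = 1.0
    intensity_log10_base: float = 7.0
    intensity_abundance_slope: float = 0.25
    intensity_log10_sigma: float = 0.45
    digest: DigestParams = DigestParams()

    def __post_init__(self) -> None:
        t = self.identity_targets
        if not t["strain"] > t["species"] > t["genus"]:
            raise ValueError("identity targets must be ordered strain > species > genus")
        if not 0 < self.id_rate <= 1:
            raise ValueError("id_rate must lie in (0, 1]")


# ---------------------------------------------------------------------------
# community fixtures


def _members(rows) -> tuple[CommunityMember, ...]:
    return tuple(CommunityMember(*r) for r in rows)


# 30 distinguishable members: two strain pairs (99% identity), one
# three-species group (95%), one three-species related-genus group (85%),
# one archaeon, one eukaryotic alga, five phages, thirteen unrelated bacteria
_UNEVEN_DESIGN: list[tuple[str, str, float, Optional[str], Optional[str]]] = [
    ("bact_01", "gram_neg", 0.30, None, None),
    ("alga_a", "eukaryote", 0.16, None, None),
    ("bact_02", "gram_pos", 0.1087, None, None),
    ("rhizobium_a", "gram_neg", 0.075, "rhizobium", "strain"),
    ("bact_03", "gram_neg", 0.055, None, None),
    ("pseudo_a", "gram_neg", 0.048, "pseudo", "species"),
    ("bact_04", "gram_pos", 0.040, None, None),
    ("staph_a", "gram_pos", 0.034, "staph", "strain"),
    ("bact_05", "gram_neg", 0.028, None, None),
    ("archaeon_a", "archaeon", 0.024, None, None),
    ("pseudo_b", "gram_neg", 0.020, "pseudo", "species"),
    ("bact_06", "gram_neg", 0.017, None, None),
    ("bact_07", "gram_pos", 0.0145, None, None),
    ("rhizobium_b", "gram_neg", 0.0125, "rhizobium", "strain"),
    ("bact_08", "gram_neg", 0.0105, None, None),
    ("nitro_a", "gram_neg", 0.009, "nitro", "genus"),
    ("bact_09", "gram_pos", 0.0078, None, None),
    ("staph_b", "gram_pos", 0.0066, "staph", "strain"),
    ("bact_10", "gram_neg", 0.0056, None, None),
    ("pseudo_c", "gram_neg", 0.0048, "pseudo", "species"),
    ("bact_11", "gram_neg", 0.0040, None, None),
    ("bact_12", "gram_pos", 0.0034, None, None),
    ("nitro_b", "gram_neg", 0.0028, "nitro", "genus"),
    ("bact_13", "gram_neg", 0.0024, None, None),
    ("phage_a", "phage", 0.0015, None, None),
    ("phage_b", "phage", 0.0013, None, None),
    ("phage_c", "phage", 0.0011, None, None),
    ("phage_d", "phage", 0.0009, None, None),
    ("phage_e", "phage", 0.0008, None, None),
    ("nitro_c", "gram_neg", 0.0008, "nitro", "genus"),
]


def _cell_fractions(classes: list[str], protein_fracs: list[float]) -> list[float]:
    cells = [f / CELL_PROTEIN_MASS[c] for c, f in zip(classes, protein_fracs)]
    total = sum(cells)
    return [c / total for c in cells]


def uneven_community() -> CommunitySpec:
    """30-member community spanning >2 orders of magnitude in protein
    fraction (minimum bacterial fraction 0.08%)."""
    classes = [r[1] for r in _UNEVEN_DESIGN]
    fracs = [r[2] for r in _UNEVEN_DESIGN]
    cells = _cell_fractions(classes, fracs)
    return CommunitySpec(
        "uneven",
        _members(
            (r[0], r[1], r[2], c, r[3], r[4]) for r, c in zip(_UNEVEN_DESIGN, cells)
        ),
    )


def equal_protein_community() -> CommunitySpec:
    """Equal protein amount for every member; phages mixed 10x lower."""
    classes = [r[1] for r in _UNEVEN_DESIGN]
    base = [0.1 if c == "phage" else 1.0 for c in classes]
    total = sum(base)
    fracs = [b / total for b in base]
    cells = _cell_fractions(classes, fracs)
    return CommunitySpec(
        "equal_protein",
        _members(
            (r[0], r[1], f, c, r[3], r[4])
            for r, f, c in zip(_UNEVEN_DESIGN, fracs, cells)
        ),
    )


def equal_cell_community() -> CommunitySpec:
    """Equal cell numbers; protein fractions follow per-cell protein mass."""
    classes = [r[1] for r in _UNEVEN_DESIGN]
    n = len(classes)
    masses = [CELL_PROTEIN_MASS[c] for c in classes]
    total = sum(masses)
    fracs = [m / total for m in masses]
    return CommunitySpec(
        "equal_cell",
        _members(
            (r[0], r[1], f, 1.0 / n, r[3], r[4])
            for r, f in zip(_UNEVEN_DESIGN, fracs)
        ),
    )


def small_equal_protein_community(n_taxa: int = 5) -> CommunitySpec:
    """Small community of unrelated bacteria at equal protein fractions —
    convenient for convergence checks at large spectra budgets."""
    frac = 1.0 / n_taxa
    return CommunitySpec(
        "equal_protein",
        _members(
            (f"eq_{i:02d}", "gram_neg", frac, frac, None, None) for i in range(n_taxa)
        ),
    )


def single_organism_spec(base: CommunitySpec, taxon_id: str) -> CommunitySpec:
    """Same membership (hence same database) with all protein input on one
    organism — a pure-culture sample searched against the community DB."""
    members = []
    for m in base.members:
        frac = 1.0 if m.taxon_id == taxon_id else 0.0
        members.append(replace(m, input_protein_fraction=frac, input_cell_fraction=frac))
    if not any(m.input_protein_fraction == 1.0 for m in members):
        raise ValueError(f"taxon {taxon_id!r} not in community spec")
    return CommunitySpec("custom", tuple(members))


# ---------------------------------------------------------------------------
# proteome simulation


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AA), size=length, p=_AA_FREQ)
    return "".join(_AA[i] for i in idx)


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [a for a in _AA if ord(a) != arr[i]]
        arr[i] = ord(choices[rng.integers(len(choices))])
    return arr.tobytes().decode()


def simulate_proteome(
    spec: CommunitySpec, config: SimulationConfig
) -> tuple[list[ProteinRecord], TaxonomyTree, dict[str, str]]:
    """Generate per-member proteomes and the supporting taxonomy tree.

    Members of a relatedness group share an ancestral proteome; each member
    mutates it at rate (1 - identity)/2 per site, so the observed pairwise
    identity between members matches the level's identity target.

    Returns (protein records, taxonomy tree, accession -> taxon_id map).
    """
    rng = np.random.default_rng(config.seed)
    proteins: list[ProteinRecord] = []
    taxon_map: dict[str, str] = {}

    groups: dict[str, list[CommunityMember]] = {}
    singles: list[CommunityMember] = []
    for m in spec.members:
        if m.relatedness_group:
            groups.setdefault(m.relatedness_group, []).append(m)
        else:
            singles.append(m)

    def lengths(n: int) -> np.ndarray:
        raw = rng.lognormal(config.protein_length_log_mean, config.protein_length_log_sigma, n)
        return np.maximum(config.min_protein_length, raw.astype(int))

    def emit(member: CommunityMember, sequences: Iterable[str]) -> None:
        for j, seq in enumerate(sequences):
            acc = f"{member.taxon_id}_p{j:04d}"
            proteins.append(ProteinRecord(acc, member.taxon_id, seq))
            taxon_map[acc] = member.taxon_id

    # relatedness groups share base proteomes (generation order is fixed by
    # sorted group / member ids for determinism)
    for gname in sorted(groups):
        members = groups[gname]
        n = config.n_proteins[members[0].organism_class]
        base = [_random_protein(rng, L) for L in lengths(n)]
        level = members[0].relatedness_level
        identity = config.identity_targets[level]
        rate = (1.0 - identity) / 2.0
        for member in members:
            emit(member, (_mutate(rng, s, rate) for s in base))
    for member in singles:
        n = config.n_proteins[member.organism_class]
        emit(member, (_random_protein(rng, L) for L in lengths(n)))

    tree = _build_tree(spec, groups)
    return proteins, tree, taxon_map


def _build_tree(
    spec: CommunitySpec, groups: dict[str, list[CommunityMember]]
) -> TaxonomyTree:
    nodes = [
        TaxonNode("d_bacteria", "Bacteria", "domain"),
        TaxonNode("d_archaea", "Archaea", "domain"),
        TaxonNode("d_eukaryota", "Eukaryota", "domain"),
        TaxonNode("d_viruses", "Viruses", "domain"),
        TaxonNode("vc_phage", "Bacteriophages", "virus_class", "d_viruses"),
    ]
    domain_of = {
        "gram_neg": "d_bacteria",
        "gram_pos": "d_bacteria",
        "archaeon": "d_archaea",
        "eukaryote": "d_eukaryota",
    }
    grouped_ids = {m.taxon_id for ms in groups.values() for m in ms}
    for gname in sorted(groups):
        members = groups[gname]
        level = members[0].relatedness_level
        domain = domain_of[members[0].organism_class]
        if level == "strain":
            nodes.append(TaxonNode(f"g_{gname}", gname, "genus", domain))
            nodes.append(TaxonNode(f"s_{gname}", gname, "species", f"g_{gname}"))
            for m in members:
                nodes.append(TaxonNode(m.taxon_id, m.taxon_id, "strain", f"s_{gname}"))
        elif level == "species":
            nodes.append(TaxonNode(f"g_{gname}", gname, "genus", domain))
            for m in members:
                nodes.append(TaxonNode(m.taxon_id, m.taxon_id, "species", f"g_{gname}"))
        else:  # genus-level relatives: sibling genera in one family
            nodes.append(TaxonNode(f"f_{gname}", gname, "family", domain))
            for m in members:
                nodes.append(TaxonNode(f"g_{m.taxon_id}", m.taxon_id, "genus", f"f_{gname}"))
                nodes.append(TaxonNode(m.taxon_id, m.taxon_id, "species", f"g_{m.taxon_id}"))
    for m in spec.members:
        if m.taxon_id in grouped_ids:
            continue
        if m.organism_class == "phage":
            nodes.append(TaxonNode(m.taxon_id, m.taxon_id, "species", "vc_phage"))
        else:
            domain = domain_of[m.organism_class]
            nodes.append(TaxonNode(f"g_{m.taxon_id}", m.taxon_id, "genus", domain))
            nodes.append(TaxonNode(m.taxon_id, m.taxon_id, "species", f"g_{m.taxon_id}"))
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# PSM simulation


def _detectability(peptide: str) -> float:
    # flow-cell-friendly lengths around 14 residues dominate; missed
    # cleavages are progressively less likely to be observed
    w = math.exp(-(((len(peptide) - 14.0) / 8.0) ** 2))
    return w * (0.25 ** count_missed_cleavages(peptide))


def simulate_psms(
    proteins: list[ProteinRecord],
    spec: CommunitySpec,
    config: SimulationConfig,
    run_id: str = "run1",
) -> tuple[pd.DataFrame, int]:
    """Simulate one acquisition of ``config.n_ms2`` MS2 spectra.

    Each spectrum yields a correct PSM with probability ``id_rate``; the
    generating protein is drawn proportionally to its taxon's input protein
    fraction times a log-normal within-taxon abundance weight, and the
    peptide from the protein's tryptic digest weighted by detectability.
    Correct PSMs score from the target distribution; a ``noise_rate``
    fraction of the remaining spectra produce false matches (half to target
    peptides, half to decoy peptides) scoring from the null distribution.
    Intensities are log-normal with a mean tied to the generating protein's
    abundance.

    Returns a raw PSM table (columns spectrum_id, run_id, peptide, score,
    intensity) and the total MS2 count. Decoy status is not included — it is
    derived against a peptide index at read time.
    """
    rng = np.random.default_rng(config.seed + 1)
    frac = {m.taxon_id: m.input_protein_fraction for m in spec.members}
    targets = [p for p in proteins if not p.is_decoy and frac.get(p.taxon_id, 0.0) > 0]
    if not targets:
        raise ValueError("no proteins with positive input fraction")

    # per-protein sampling probability and digest pools
    weights = np.empty(len(targets))
    by_taxon: dict[str, list[int]] = {}
    for i, p in enumerate(targets):
        by_taxon.setdefault(p.taxon_id, []).append(i)
    for taxon, idxs in sorted(by_taxon.items()):
        w = rng.lognormal(0.0, config.abundance_sigma, len(idxs))
        w = w / w.sum() * frac[taxon]
        weights[idxs] = w
    weights = weights / weights.sum()

    d = config.digest
    pools: list[tuple[list[str], np.ndarray]] = []
    for p in targets:
        peps = digest(p.sequence, d.enzyme, d.missed_cleavages, d.min_len, d.max_len)
        if not peps:
            pools.append(([], np.empty(0)))
            continue
        w = np.array([_detectability(q) for q in peps])
        pools.append((peps, w / w.sum()))

    n_target = rng.binomial(config.n_ms2, config.id_rate)
    counts = rng.multinomial(n_target, weights)
    # intensity-dependent detection efficiency (saturates for abundant
    # proteins, thins candidates near the limit of detection)
    detect = weights / (weights + config.lod_weight)
    counts = rng.binomial(counts, detect)
    peptides: list[str] = []
    prot_idx: list[int] = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        peps, w = pools[i]
        if not peps:
            continue
        picks = rng.choice(len(peps), size=c, p=w)
        peptides.extend(peps[j] for j in picks)
        prot_idx.extend([i] * c)
    n_real = len(peptides)
    scores = rng.normal(config.target_score_mu, config.target_score_sigma, n_real)
    log_w = np.log10(weights[np.asarray(prot_idx, dtype=int)])
    log_w_centered = log_w - log_w.mean() if n_real else log_w
    intensities = 10.0 ** (
        config.intensity_log10_base
        + config.intensity_abundance_slope * log_w_centered
        + rng.normal(0.0, config.intensity_log10_sigma, n_real)
    )

    # false matches: unexplained spectra occasionally match a random peptide
    # anywhere in the searched database (half target, half decoy), not just
    # in the organisms actually present in the sample
    n_noise = rng.binomial(config.n_ms2 - n_target, config.noise_rate)
    all_targets = [p for p in proteins if not p.is_decoy]
    target_pool = sorted(
        {
            q
            for p in all_targets
            for q in digest(p.sequence, d.enzyme, d.missed_cleavages, d.min_len, d.max_len)
        }
    )
    decoy_pool = sorted(
        {
            q
            for p in generate_decoys(all_targets)
            for q in digest(p.sequence, d.enzyme, d.missed_cleavages, d.min_len, d.max_len)
        }
    )
    noise_is_decoy = rng.random(n_noise) < 0.5
    noise_peps = [
        decoy_pool[rng.integers(len(decoy_pool))]
        if dec and decoy_pool
        else target_pool[rng.integers(len(target_pool))]
        for dec in noise_is_decoy
    ]
    noise_scores = rng.normal(config.null_score_mu, config.null_score_sigma, n_noise)
    noise_intensities = 10.0 ** (
        config.intensity_log10_base - 0.5 + rng.normal(0.0, 0.5, n_noise)
    )

    all_peps = peptides + noise_peps
    all_scores = np.concatenate([scores, noise_scores])
    all_int = np.concatenate([intensities, noise_intensities])
    n = len(all_peps)
    df = pd.DataFrame(
        {
            "spectrum_id": [f"sp{i:07d}" for i in range(n)],
            "run_id": run_id,
            "peptide": all_peps,
            "score": np.round(all_scores, 6),
            "intensity": np.round(all_int, 3),
        }
    )
    return df, config.n_ms2


def make_incomplete_db(
    proteins: Iterable[ProteinRecord], drop: Iterable[str]
) -> list[ProteinRecord]:
    """Database subset with all records of the dropped taxa removed."""
    dropped = set(drop)
    return [p for p in proteins if p.taxon_id not in dropped]


# ---------------------------------------------------------------------------
# relatedness-scenario benchmark bundles


@dataclass
class ScenarioBundle:
    scenario: str  # strain | species | genus | unrelated
    analyzed_taxon: str
    truth_taxa: frozenset[str]
    psms_raw: pd.DataFrame
    total_ms2: int


def scenario_fig2(
    config: SimulationConfig,
    db_spec: Optional[CommunitySpec] = None,
) -> tuple[list[ProteinRecord], TaxonomyTree, dict[str, str], dict[str, ScenarioBundle]]:
    """Four pure-culture benchmark bundles against one 30-taxon database.

    The analyzed organisms have, in the shared database, (strain) a
    near-identical strain sibling, (species) congeneric species at ~95%
    identity, (genus) related genera at ~85% identity, and (unrelated) no
    relative at all — the lone archaeon.
    """
    spec = db_spec or uneven_community()
    proteins, tree, taxon_map = simulate_proteome(spec, config)
    cases = {
        "strain": "rhizobium_a",
        "species": "pseudo_a",
        "genus": "nitro_a",
        "unrelated": "archaeon_a",
    }
    bundles: dict[str, ScenarioBundle] = {}
    for i, (scenario, taxon) in enumerate(cases.items()):
        sample = single_organism_spec(spec, taxon)
        cfg = replace(config, seed=config.seed + 101 + i)
        psms, total = simulate_psms(proteins, sample, cfg, run_id=f"{scenario}_run")
        bundles[scenario] = ScenarioBundle(
            scenario, taxon, frozenset({taxon}), psms, total
        )
    return proteins, tree, taxon_map, bundles


# ---------------------------------------------------------------------------
# convenience


def simulate_community_bundle(
    spec: CommunitySpec,
    config: SimulationConfig,
    index: Optional[PeptideIndex] = None,
):
    """Proteome + decoys + index + finalized PSM frame for one community.

    Returns (proteins_with_decoys, tree, taxon_map, index, psms, total_ms2).
    """
    proteins, tree, taxon_map = simulate_proteome(spec, config)
    db = proteins + generate_decoys(proteins)
    if index is None:
        index = build_peptide_index(db, config.digest)
    raw, total_ms2 = simulate_psms(proteins, spec, config)
    psms = psm_frame_from_arrays(
        index,
        raw["spectrum_id"].to_numpy(),
        raw["run_id"].to_numpy(),
        raw["peptide"].tolist(),
        raw["score"].to_numpy(),
        raw["intensity"].to_numpy(),
    )
    return db, tree, taxon_map, index, psms, total_ms2
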