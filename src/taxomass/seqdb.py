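"""Protein sequence databases: loading, taxonomy, digestion, indexing, decoys.

The peptide index built here is the central data structure of the whole
workflow: it records, for every tryptic peptide, the set of protein
accessions it occurs in.  Peptide sharing between proteins of related
organisms is what creates the protein inference problem downstream, so the
index must cover targets and decoys alike and must use a single peptide
canonicalization rule everywhere (I and L have identical mass and are
replaced by L before keying).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: reserved accession prefix for reversed decoy sequences
DECOY_PREFIX = "REV_"

#: taxonomic ranks, finest to coarsest; parents must be strictly coarser
RANKS = ("strain", "species", "genus", "family", "virus_class", "phylum", "domain")
_RANK_ORDER = {r: i for i, r in enumerate(RANKS)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def canonicalize(peptide: str) -> str:
    """Canonical peptide form: uppercase, isoleucine folded onto leucine.

    I and L are indistinguishable by mass, so all peptide keys (index,
    PSM tables, grouping) use the folded form.
    """
    return peptide.upper().replace("I", "L")


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rank not in _RANK_ORDER:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {RANKS}")


class TaxonomyTree:
    """Validated collection of :class:`TaxonNode` with ancestor lookup."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon_id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node
        for node in self.nodes.values():
            if node.parent_id is None:
                continue
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise ValueError(
                    f"taxon {node.taxon_id!r} references missing parent {node.parent_id!r}"
                )
            if _RANK_ORDER[parent.rank] <= _RANK_ORDER[node.rank]:
                raise ValueError(
                    f"parent {parent.taxon_id!r} ({parent.rank}) not strictly above "
                    f"child {node.taxon_id!r} ({node.rank})"
                )
        # rank ordering along parent edges is strictly increasing, so cycles
        # are impossible once the check above passes

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str:
        """Taxon id of the ancestor at *rank* (the taxon itself if it already
        is at that rank, or if no ancestor of that rank exists on its lineage,
        e.g. viral taxa asked for a genus)."""
        if rank not in _RANK_ORDER:
            raise ValueError(f"unknown rank {rank!r}")
        node = self.nodes[taxon_id]
        while True:
            if node.rank == rank:
                return node.taxon_id
            if _RANK_ORDER[node.rank] > _RANK_ORDER[rank]:
                return taxon_id
            if node.parent_id is None:
                return taxon_id
            node = self.nodes[node.parent_id]

    def name_of(self, taxon_id: str) -> str:
        node = self.nodes.get(taxon_id)
        return node.name if node is not None else taxon_id

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (n.taxon_id, n.name, n.rank, n.parent_id if n.parent_id else "")
            for n in self.nodes.values()
        ]
        pd.DataFrame(rows, columns=["taxon_id", "name", "rank", "parent_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        nodes = [
            TaxonNode(r.taxon_id, r.name, r.rank, r.parent_id or None)
            for r in df.itertuples()
        ]
        return cls(nodes)


def read_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Accession -> taxon_id map from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "taxon_id"):
        if col not in df.columns:
            raise ValueError(f"taxonomy map missing required column {col!r}")
    return dict(zip(df["accession"], df["taxon_id"]))


def write_taxonomy_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["accession", "taxon_id"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein records


@dataclass
class ProteinRecord:
    accession: str
    taxon_id: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")


def read_fasta(
    path: str | Path,
    taxonomy: Mapping[str, str],
    default_taxon: Optional[str] = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Every accession (first whitespace-separated token of the header) must be
    present in *taxonomy* unless *default_taxon* is given.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        taxon = taxonomy.get(accession, default_taxon)
        if taxon is None:
            raise KeyError(
                f"accession {accession!r} has no taxonomy entry and no default taxon is set"
            )
        records.append(ProteinRecord(accession, taxon, str(entry.seq).upper()))
    if not records:
        logger.warning("FASTA file %s contained no entries", path)
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="") for p in proteins
    ]
    SeqIO.write(entries, str(path), "fasta")


def generate_decoys(proteins: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, accession prefixed.

    Decoys keep the source taxon for bookkeeping but are excluded from all
    abundance outputs downstream.
    """
    decoys = []
    n_palindromic = 0
    for p in proteins:
        rev = p.sequence[::-1]
        if rev == p.sequence:
            n_palindromic += 1
        decoys.append(ProteinRecord(DECOY_PREFIX + p.accession, p.taxon_id, rev, True))
    if n_palindromic:
        logger.warning(
            "%d palindromic sequence(s): decoy equals target", n_palindromic
        )
    return decoys


def remove_exact_duplicates(
    proteins: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Collapse sequence-identical records onto the first-seen accession."""
    kept: list[ProteinRecord] = []
    seen: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for p in proteins:
        rep = seen.get(p.sequence)
        if rep is None:
            seen[p.sequence] = p.accession
            kept.append(p)
        else:
            dropped[p.accession] = rep
    return kept, dropped


# ---------------------------------------------------------------------------
# digestion & indexing


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    min_len: int = 6
    max_len: int = 50


_ENZYMES = ("trypsin",)


def digest(
    sequence: str,
    enzyme: str = "trypsin",
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> list[str]:
    """In-silico digestion; trypsin cleaves C-terminal of K/R except before P.

    Peptides with up to *missed_cleavages* internal sites are produced, in
    order of their start position.  Windows containing the undefined residue
    X are skipped (they cannot be matched by mass).
    """
    if enzyme not in _ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; known: {_ENZYMES}")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    seq = sequence.upper()
    n = len(seq)
    sites = [i + 1 for i in range(n - 1) if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + sites + [n]
    frags = [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: list[str] = []
    for i in range(len(frags)):
        pep = ""
        for k in range(missed_cleavages + 1):
            if i + k >= len(frags):
                break
            pep += frags[i + k]
            if min_len <= len(pep) <= max_len and "X" not in pep:
                peptides.append(pep)
    return peptides


def count_missed_cleavages(peptide: str) -> int:
    """Number of internal tryptic sites in a peptide (K/R not followed by P)."""
    return sum(
        1
        for i in range(len(peptide) - 1)
        if peptide[i] in "KR" and peptide[i + 1] != "P"
    )


class PeptideIndex:
    """Canonical peptide -> protein accession map for a digested database."""

    def __init__(
        self,
        mapping: Mapping[str, frozenset[str]],
        params: DigestParams,
        canonicalization: str = "I->L",
    ):
        self._map: dict[str, frozenset[str]] = dict(mapping)
        self.params = params
        self.canonicalization = canonicalization

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._map

    def __len__(self) -> int:
        return len(self._map)

    def peptides(self) -> Iterable[str]:
        return self._map.keys()

    def accessions_for(self, peptide: str) -> frozenset[str]:
        return self._map.get(peptide, frozenset())

    def is_protein_unique(self, peptide: str) -> bool:
        """True if the peptide occurs in exactly one protein sequence
        database-wide (targets and decoys)."""
        return len(self._map.get(peptide, ())) == 1

    def decoy_only(self, peptide: str) -> bool:
        accs = self._map.get(peptide)
        if not accs:
            return False
        return all(a.startswith(DECOY_PREFIX) for a in accs)

    def to_tsv(self, path: str | Path) -> None:
        rows = (
            (pep, ";".join(sorted(accs))) for pep, accs in sorted(self._map.items())
        )
        pd.DataFrame(rows, columns=["peptide", "accessions"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, params: Optional[DigestParams] = None) -> "PeptideIndex":
        df = pd.read_csv(path, sep="\t", dtype=str)
        mapping = {
            r.peptide: frozenset(r.accessions.split(";")) for r in df.itertuples()
        }
        return cls(mapping, params or DigestParams())


def build_peptide_index(
    proteins: Iterable[ProteinRecord], params: DigestParams = DigestParams()
) -> PeptideIndex:
    """Digest every protein (targets and decoys) and index its peptides."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("cannot build a peptide index from an empty protein list")
    mapping: dict[str, set[str]] = defaultdict(set)
    for p in proteins:
        for pep in digest(
            p.sequence,
            params.enzyme,
            params.missed_cleavages,
            params.min_len,
            params.max_len,
        ):
            mapping[canonicalize(pep)].add(p.accession)
    return PeptideIndex(
        {pep: frozenset(accs) for pep, accs in mapping.items()}, params
    )
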