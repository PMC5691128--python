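"""Mock-community simulator: specs, proteomes, PSM generation, determinism."""

import numpy as np
import pytest

from taxomass.evaluation import CommunityTruth
from taxomass.psm_io import psm_frame_from_arrays, psm_fdr_filter
from taxomass.seqdb import build_peptide_index, generate_decoys
from taxomass.simulate import (
    CommunitySpec,
    SimulationConfig,
    equal_cell_community,
    equal_protein_community,
    make_incomplete_db,
    simulate_proteome,
    simulate_psms,
    single_organism_spec,
    small_equal_protein_community,
    uneven_community,
)


class TestCommunitySpecs:
    @pytest.mark.parametrize(
        "factory", [uneven_community, equal_protein_community, equal_cell_community]
    )
    def test_fixture_fractions_are_valid_truth_tables(self, factory):
        spec = factory()
        assert len(spec.members) == 30
        truth = spec.truth()
        assert isinstance(truth, CommunityTruth)

    def test_uneven_design_spans_two_orders_of_magnitude(self):
        spec = uneven_community()
        fracs = [m.input_protein_fraction for m in spec.members]
        assert max(fracs) / min(fracs) >= 100
        bacteria = [
            m.input_protein_fraction
            for m in spec.members
            if m.organism_class in ("gram_neg", "gram_pos")
        ]
        assert min(bacteria) == pytest.approx(0.0008)

    def test_equal_protein_mixes_phages_ten_fold_lower(self):
        spec = equal_protein_community()
        phage = {m.input_protein_fraction for m in spec.members if m.organism_class == "phage"}
        other = {m.input_protein_fraction for m in spec.members if m.organism_class != "phage"}
        assert len(phage) == 1 and len(other) == 1
        assert next(iter(other)) / next(iter(phage)) == pytest.approx(10.0)

    def test_invalid_fraction_sum_rejected(self):
        from taxomass.simulate import CommunityMember

        with pytest.raises(ValueError, match="sum to 1"):
            CommunitySpec(
                "custom",
                (CommunityMember("x", "gram_neg", 0.5, 1.0),),
            )


class TestProteome:
    def test_identity_target_reached(self):
        spec = uneven_community()
        config = SimulationConfig(seed=2)
        proteins, tree, taxon_map = simulate_proteome(spec, config)
        by_taxon = {}
        for p in proteins:
            by_taxon.setdefault(p.taxon_id, []).append(p.sequence)

        def pairwise_identity(a, b):
            pairs = [
                (x, y) for sa, sb in zip(a, b) for x, y in zip(sa, sb)
            ]
            return sum(1 for x, y in pairs if x == y) / len(pairs)

        strain = pairwise_identity(by_taxon["rhizobium_a"], by_taxon["rhizobium_b"])
        species = pairwise_identity(by_taxon["pseudo_a"], by_taxon["pseudo_b"])
        genus = pairwise_identity(by_taxon["nitro_a"], by_taxon["nitro_b"])
        assert strain == pytest.approx(0.99, abs=0.02)
        assert species == pytest.approx(0.95, abs=0.02)
        assert genus == pytest.approx(0.85, abs=0.02)
        assert strain > species > genus

    def test_strain_pair_shares_majority_of_peptides(self):
        spec = uneven_community()
        proteins, _, _ = simulate_proteome(spec, SimulationConfig(seed=2))
        pair = [p for p in proteins if p.taxon_id in ("rhizobium_a", "rhizobium_b")]
        index = build_peptide_index(pair)
        shared = sum(1 for pep in index.peptides() if len({
            "a" if a.startswith("rhizobium_a") else "b" for a in index.accessions_for(pep)
        }) == 2)
        assert shared / len(index) > 0.5

    def test_unrelated_taxa_share_almost_nothing(self):
        spec = uneven_community()
        proteins, _, _ = simulate_proteome(spec, SimulationConfig(seed=2))
        pair = [p for p in proteins if p.taxon_id in ("bact_01", "bact_02")]
        index = build_peptide_index(pair)
        shared = sum(
            1
            for pep in index.peptides()
            if len({a.split("_p")[0] for a in index.accessions_for(pep)}) == 2
        )
        assert shared / len(index) < 0.01

    def test_taxonomy_covers_every_member(self):
        spec = uneven_community()
        _, tree, taxon_map = simulate_proteome(spec, SimulationConfig(seed=2))
        for m in spec.members:
            assert m.taxon_id in tree
        assert set(taxon_map.values()) == {m.taxon_id for m in spec.members}


class TestPsmSimulation:
    def test_accepted_count_within_binomial_bounds(self):
        spec = small_equal_protein_community()
        config = SimulationConfig(seed=4, n_ms2=1000, noise_rate=0.0)
        proteins, _, _ = simulate_proteome(spec, config)
        psms, total = simulate_psms(proteins, spec, config)
        mean = 1000 * config.id_rate
        sd = np.sqrt(1000 * config.id_rate * (1 - config.id_rate))
        assert abs(len(psms) - mean) < 5 * sd
        assert total == 1000

    def test_single_taxon_sample_generates_only_its_peptides(self):
        spec = single_organism_spec(small_equal_protein_community(), "eq_00")
        config = SimulationConfig(seed=4, n_ms2=2000, noise_rate=0.0)
        proteins, _, taxon_map = simulate_proteome(small_equal_protein_community(), config)
        psms, _ = simulate_psms(proteins, spec, config)
        index = build_peptide_index(proteins, config.digest)
        from taxomass.seqdb import canonicalize

        for pep in psms["peptide"].unique():
            taxa = {taxon_map[a] for a in index.accessions_for(canonicalize(pep))}
            assert taxa == {"eq_00"}

    def test_doubling_spectra_never_loses_detections(self):
        spec = uneven_community()
        config_lo = SimulationConfig(seed=6, n_ms2=4000)
        config_hi = SimulationConfig(seed=6, n_ms2=8000)
        proteins, _, taxon_map = simulate_proteome(spec, config_lo)
        index = build_peptide_index(proteins, config_lo.digest)
        from taxomass.seqdb import canonicalize

        def detected_taxa(config):
            psms, _ = simulate_psms(proteins, spec, config)
            taxa = set()
            for pep in psms["peptide"].unique():
                owners = {taxon_map[a] for a in index.accessions_for(canonicalize(pep))}
                if len(owners) == 1:
                    taxa |= owners
            return taxa

        assert len(detected_taxa(config_lo)) <= len(detected_taxa(config_hi))

    def test_determinism_byte_identical_outputs(self, tmp_path):
        from taxomass.seqdb import write_fasta

        spec = small_equal_protein_community()
        config = SimulationConfig(seed=8, n_ms2=3000)
        out = []
        for tag in ("x", "y"):
            proteins, _, _ = simulate_proteome(spec, config)
            psms, _ = simulate_psms(proteins, spec, config)
            fasta = tmp_path / f"{tag}.fasta"
            table = tmp_path / f"{tag}.tsv"
            write_fasta(proteins, fasta)
            psms.to_csv(table, sep="\t", index=False)
            out.append((fasta.read_bytes(), table.read_bytes()))
        assert out[0] == out[1]


class TestIncompleteDb:
    def test_drop_nothing_is_identity(self, toy_proteins):
        assert make_incomplete_db(toy_proteins, set()) == toy_proteins

    def test_dropped_taxon_accessions_absent(self, toy_proteins):
        sub = make_incomplete_db(toy_proteins, {"taxA"})
        assert {p.taxon_id for p in sub} == {"taxB"}

    def test_dropped_strain_signal_shifts_to_sibling(self):
        """Removing one strain re-annotates its shared peptides to the
        retained sibling."""
        spec = uneven_community()
        config = SimulationConfig(seed=9, n_ms2=20_000)
        proteins, _, taxon_map = simulate_proteome(spec, config)
        db = proteins + generate_decoys(proteins)
        index_full = build_peptide_index(db, config.digest)
        sub = make_incomplete_db(db, {"rhizobium_a"})
        index_sub = build_peptide_index(sub, config.digest)
        psms_raw, _ = simulate_psms(proteins, spec, config)

        def sibling_psms(index):
            psms = psm_frame_from_arrays(
                index,
                psms_raw["spectrum_id"].to_numpy(),
                psms_raw["run_id"].to_numpy(),
                psms_raw["peptide"].tolist(),
                psms_raw["score"].to_numpy(),
            )
            acc, _ = psm_fdr_filter(psms, 0.01)
            count = 0
            for pep in acc["peptide"]:
                owners = {
                    taxon_map.get(a) for a in index.accessions_for(pep) if a in taxon_map
                }
                if owners == {"rhizobium_b"}:
                    count += 1
            return count

        assert sibling_psms(index_sub) > sibling_psms(index_full)
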