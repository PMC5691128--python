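"""Protein grouping, the two scoring engines, and the strategy algebra."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_fido, make_group
from taxomass.inference import (
    STRATEGIES,
    FidoParams,
    apply_inference_strategy,
    fido_posteriors,
    group_proteins,
    protein_unique_peptide_counts,
    score_protein_groups_engineA,
    unique_peptide_counts,
)
from taxomass.seqdb import DigestParams, PeptideIndex


def index_from(mapping):
    return PeptideIndex(
        {p: frozenset(a) for p, a in mapping.items()}, DigestParams()
    )


class TestGrouping:
    def test_identical_peptide_sets_merge(self):
        index = index_from({"AAA": ["P1", "P2"], "BBB": ["P1", "P2"]})
        groups = group_proteins(["AAA", "BBB"], index)
        assert len(groups) == 1
        assert groups[0].members == ("P1", "P2")
        assert groups[0].principal == ("P1", "P2")
        assert groups[0].leading == "P1"

    def test_subset_protein_absorbed(self):
        index = index_from({"AAA": ["P3", "P4"], "BBB": ["P4"]})
        groups = group_proteins(["AAA", "BBB"], index)
        assert len(groups) == 1
        g = groups[0]
        assert set(g.members) == {"P3", "P4"}
        assert g.principal == ("P4",)  # P3's evidence is a strict subset
        assert g.peptides == frozenset({"AAA", "BBB"})

    def test_overlapping_sets_stay_separate(self):
        index = index_from({"AAA": ["P5"], "SHR": ["P5", "P6"], "CCC": ["P6"]})
        groups = group_proteins(["AAA", "SHR", "CCC"], index)
        assert len(groups) == 2
        assert {g.peptides for g in groups} == {
            frozenset({"AAA", "SHR"}),
            frozenset({"SHR", "CCC"}),
        }

    def test_taxa_follow_principal_members(self):
        index = index_from({"AAA": ["P1", "P2"], "BBB": ["P1"]})
        groups = group_proteins(
            ["AAA", "BBB"], index, {"P1": "taxA", "P2": "taxB"}
        )
        (g,) = groups
        assert g.taxon_ids == frozenset({"taxA"})

    def test_decoy_only_group_flagged(self):
        index = index_from({"AAA": ["REV_P1"]})
        (g,) = group_proteins(["AAA"], index)
        assert g.is_decoy


class TestPeptideCounts:
    def test_unique_peptides_exclude_shared(self):
        g1 = make_group("G1", {"A", "B", "S"})
        g2 = make_group("G2", {"C", "S"})
        counts = unique_peptide_counts([g1, g2])
        assert counts == {"G1": 2, "G2": 1}

    def test_single_group_owns_all_its_peptides(self):
        g = make_group("G1", {"A", "B", "C"})
        assert unique_peptide_counts([g]) == {"G1": 3}

    def test_protein_unique_requires_single_accession_database_wide(self):
        index = index_from(
            {"A": ["P1"], "S": ["P1", "P2"], "D": ["P1", "REV_P9"]}
        )
        g = make_group("G1", {"A", "S", "D"})
        # S is shared between targets; D is shared with a decoy: neither counts
        assert protein_unique_peptide_counts([g], index) == {"G1": 1}


class TestEngineA:
    def _psms(self, rows):
        return pd.DataFrame(
            {
                "spectrum_id": [f"s{i}" for i in range(len(rows))],
                "run_id": "r1",
                "peptide": [r[0] for r in rows],
                "engine": "A",
                "score": [r[1] for r in rows],
                "intensity": np.nan,
                "is_decoy": False,
            }
        )

    def test_score_is_sum_of_best_psm_per_peptide(self):
        g = make_group("G1", {"A", "B"})
        psms = self._psms([("A", 10.0), ("A", 4.0), ("B", 7.0)])
        scored = score_protein_groups_engineA([g], psms)
        assert scored.loc[0, "score_a"] == 17.0
        assert scored.loc[0, "psm_count"] == 3

    def test_hand_enumerated_group_qvalues(self):
        # ranking: T1 (20) > D1 (15) > T2 (10)
        # FDR depths: 0/1, 1/1, 1/2 -> q = 0, 0.5, 0.5
        groups = [
            make_group("T1", {"A"}),
            make_group("D1", {"B"}, decoy=True),
            make_group("T2", {"C"}),
        ]
        psms = self._psms([("A", 20.0), ("B", 15.0), ("C", 10.0)])
        scored = score_protein_groups_engineA(groups, psms).set_index("group_id")
        assert scored.loc["T1", "q_a"] == 0.0
        assert scored.loc["T2", "q_a"] == 0.5

    def test_no_decoys_means_zero_qvalues(self):
        groups = [make_group("T1", {"A"}), make_group("T2", {"B"})]
        psms = self._psms([("A", 5.0), ("B", 1.0)])
        assert (score_protein_groups_engineA(groups, psms)["q_a"] == 0).all()


class TestFido:
    def test_single_group_closed_form(self):
        params = FidoParams(alpha=0.9, beta=0.01, gamma=0.5)
        post = fido_posteriors([make_group("P", {"pep"})], {"pep": 1.0}, params)
        expected = (0.5 * 0.901) / (0.5 * 0.901 + 0.5 * 0.01)
        assert post["P"] == pytest.approx(expected, abs=1e-12)

    def test_no_evidence_returns_prior(self):
        params = FidoParams(gamma=0.3)
        post = fido_posteriors([make_group("P", {"pep"})], {"pep": 0.0}, params)
        assert post["P"] == pytest.approx(0.3, abs=1e-12)
        assert fido_posteriors([make_group("Q", {"x"})], {}, params)["Q"] == 0.3

    def test_shared_only_peptide_gives_symmetric_posteriors(self):
        params = FidoParams()
        post = fido_posteriors(
            [make_group("A", {"s"}), make_group("B", {"s"})], {"s": 0.95}, params
        )
        assert post["A"] == pytest.approx(post["B"], abs=1e-12)

    def test_matches_enumeration_oracle_on_random_components(self):
        rng = np.random.default_rng(123)
        params = FidoParams(alpha=0.85, beta=0.02, gamma=0.4)
        for _ in range(25):
            k = int(rng.integers(1, 9))
            n_pep = int(rng.integers(1, 15))
            graph = {
                f"G{i}": {
                    f"p{j}" for j in range(n_pep) if rng.random() < 0.4
                }
                for i in range(k)
            }
            probs = {f"p{j}": float(rng.random()) for j in range(n_pep)}
            groups = [make_group(g, peps or {f"lone_{g}"}) for g, peps in graph.items()]
            probs.update({f"lone_{g}": 0.5 for g in graph})
            ours = fido_posteriors(groups, probs, params)
            oracle = brute_force_fido(
                {g.group_id: g.peptides for g in groups}, probs,
                params.alpha, params.beta, params.gamma,
            )
            for gid in ours:
                assert ours[gid] == pytest.approx(oracle[gid], abs=1e-9)

    def test_oversized_component_is_pruned_not_dropped(self):
        params = FidoParams(max_exact_component=3, pruning_floor=0.2)
        groups = [make_group(f"G{i}", {f"own{i}", "shared"}) for i in range(6)]
        probs = {f"own{i}": 0.9 for i in range(6)}
        probs["shared"] = 0.05  # below the pruning floor
        post = fido_posteriors(groups, probs, params)
        assert set(post) == {g.group_id for g in groups}
        assert all(0 < p < 1 for p in post.values())

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            FidoParams(alpha=1.5)


class TestStrategies:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["group_id", "q_a", "q_b", "n_up", "n_pup", "is_decoy"],
        )

    def test_pup_requirement_rejects_single_pup_group(self):
        t = self._table([("G1", 0.001, 0.02, 3, 1, False)])
        assert "G1" in apply_inference_strategy("FIDO_5FDR", t).accepted
        assert "G1" not in apply_inference_strategy("2PUP_FIDO", t).accepted

    def test_three_pup_rescues_group_missed_by_second_engine(self):
        t = self._table([("G1", 0.5, 0.03, 1, 3, False)])
        assert "G1" not in apply_inference_strategy("FIDO_AND_B2", t).accepted
        assert "G1" in apply_inference_strategy("FIDO_AND_B2_OR_3PUP", t).accepted

    def test_decoy_groups_never_accepted(self):
        t = self._table([("D1", 0.0, 0.0, 9, 9, True)])
        for name in STRATEGIES:
            assert not apply_inference_strategy(name, t).accepted

    def test_unknown_strategy_lists_valid_names(self):
        with pytest.raises(ValueError, match="2PUP_FIDO"):
            apply_inference_strategy("nope", self._table([]))

    def test_nesting_on_random_tables(self):
        rng = np.random.default_rng(99)
        t = self._table(
            [
                (
                    f"G{i}",
                    float(rng.random() * 0.1),
                    float(rng.random() * 0.1),
                    int(rng.integers(0, 5)),
                    int(rng.integers(0, 5)),
                    bool(rng.random() < 0.1),
                )
                for i in range(300)
            ]
        )
        acc = {n: apply_inference_strategy(n, t).accepted for n in STRATEGIES}
        assert acc["2UP"] <= acc["SQ_5FDR"]
        assert acc["2PUP_FIDO"] <= acc["FIDO_5FDR"]
        assert acc["2PUP_FIDO_AND_B2"] <= acc["FIDO_AND_B2"] <= acc["FIDO_5FDR"]
        assert acc["FIDO_AND_B2"] <= acc["FIDO_AND_B2_OR_3PUP"]
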