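"""Network construction, validation, and the circuit library."""

import numpy as np
import pytest

from totalnoise import (
    NetworkSpecError,
    circuit_post_transcriptional,
    circuit_post_transcriptional_hill,
    circuit_single_gene,
    circuit_transcriptional_autoreg,
    evaluate_propensities,
    make_network,
    network_from_config,
    steady_state_lna,
)


class TestMakeNetwork:
    def test_valid_two_species_four_reactions(self, single_gene):
        assert single_gene.n_species == 2
        assert single_gene.n_reactions == 4
        assert single_gene.stoichiometry.shape == (2, 4)

    def test_undeclared_symbol_named_in_error(self):
        with pytest.raises(NetworkSpecError, match="'Q'"):
            make_network(["R"], [[1]], ["k * Q"], {"k": 1.0})

    def test_column_count_mismatch(self):
        with pytest.raises(NetworkSpecError, match="3 stoichiometry columns but 4"):
            make_network(
                ["R"], [[1, -1, 1]], ["k", "k", "k", "k"], {"k": 1.0}
            )

    def test_non_integer_stoichiometry(self):
        with pytest.raises(NetworkSpecError, match="integer"):
            make_network(["R"], [[0.5]], ["k"], {"k": 1.0})

    def test_non_positive_system_size(self):
        with pytest.raises(NetworkSpecError, match="system size"):
            make_network(["R"], [[1]], ["k"], {"k": 1.0}, system_size=0)

    def test_non_positive_parameter(self):
        with pytest.raises(NetworkSpecError, match="'k'"):
            make_network(["R"], [[1]], ["k"], {"k": -1.0})


class TestPropensities:
    def test_birth_death_values(self):
        net = make_network(
            ["R"], [[1, -1]], ["k_R * D0", "gamma_R * R"],
            {"k_R": 10.0, "gamma_R": 0.1}, {"D0": 1.0},
        )
        assert evaluate_propensities(net, [50.0]) == pytest.approx([10.0, 5.0])

    def test_hill_half_maximal_at_K_any_n(self):
        for n in (1, 2, 3, 4):
            net = circuit_transcriptional_autoreg(n=n, K=200.0)
            f = evaluate_propensities(net, [0.0, 200.0])
            assert f[0] == pytest.approx(0.5)  # k_R*D0/2 at P = K

    def test_negative_state_rejected(self, single_gene):
        with pytest.raises(NetworkSpecError, match="negative state"):
            evaluate_propensities(single_gene, [-1.0, 0.0])

    def test_nonnegative_on_orthant(self, rng):
        nets = [
            circuit_single_gene(),
            circuit_transcriptional_autoreg(n=3, K=50.0),
            circuit_post_transcriptional(),
            circuit_post_transcriptional(transcript_mode="separate"),
            circuit_post_transcriptional_hill(n_m=2, K_m=20.0),
        ]
        for net in nets:
            for _ in range(20):
                x = rng.uniform(0, 500, size=net.n_species)
                assert np.all(evaluate_propensities(net, x) >= 0)


class TestCircuits:
    def test_single_gene_structure(self, single_gene):
        # translation produces one protein and consumes nothing
        j = single_gene.reaction_names.index("translation")
        assert list(single_gene.stoichiometry[:, j]) == [0, 1]
        assert evaluate_propensities(single_gene, [0.0, 0.0])[j] == 0.0

    def test_autoreg_no_feedback_limit_matches_single_gene(self, rng):
        auto = circuit_transcriptional_autoreg(n=4, K=np.inf)
        sg = circuit_single_gene()
        for _ in range(10):
            x = rng.uniform(0, 1000, size=2)
            np.testing.assert_allclose(
                evaluate_propensities(auto, x), evaluate_propensities(sg, x)
            )

    def test_autoreg_rejects_bad_hill(self):
        with pytest.raises(ValueError):
            circuit_transcriptional_autoreg(n=0)
        with pytest.raises(ValueError):
            circuit_transcriptional_autoreg(K=-1.0)

    def test_same_transcript_coproduction_column(self):
        net = circuit_post_transcriptional(transcript_mode="same")
        j = net.reaction_names.index("transcription")
        assert list(net.stoichiometry[:, j]) == [1, 1, 0, 0]

    def test_mirna_recycled_on_induced_degradation(self):
        net = circuit_post_transcriptional()
        j = net.reaction_names.index("induced_deg")
        # complex consumed, miRNA released, mRNA lost with the complex
        assert list(net.stoichiometry[:, j]) == [0, 1, -1, 0]

    def test_unknown_transcript_mode(self):
        with pytest.raises(ValueError, match="transcript_mode"):
            circuit_post_transcriptional(transcript_mode="both")

    def test_kb_zero_protein_mean_matches_single_gene(self):
        """With no binding the macroscopic protein steady state must equal the
        plain two-stage circuit's k_R k_P D0 / (gamma_R gamma_P)."""
        post = circuit_post_transcriptional(theta={"k_b": 0.0})
        sg = circuit_single_gene()
        m_post = steady_state_lna(post).mean_of("P")
        m_sg = steady_state_lna(sg).mean_of("P")
        assert m_post == pytest.approx(m_sg, rel=1e-8)
        assert m_sg == pytest.approx(1.0 * 1.0 * 1.0 / (0.1 * 0.01), rel=1e-8)

    def test_hill_mirna_structure_and_limits(self):
        net = circuit_post_transcriptional_hill(n_m=2, K_m=50.0)
        assert net.n_species == 3
        # translation halves at M = K_m
        j = net.reaction_names.index("translation")
        f = evaluate_propensities(net, [10.0, 50.0, 0.0])
        assert f[j] == pytest.approx(10.0 * 0.5)
        # K_m -> inf: translation unrepressed, M an uncoupled birth-death
        free = circuit_post_transcriptional_hill(n_m=2, K_m=np.inf)
        f = evaluate_propensities(free, [10.0, 1e6, 0.0])
        assert f[free.reaction_names.index("translation")] == pytest.approx(10.0)

    def test_stoichiometry_entries_bounded(self):
        for net in (
            circuit_single_gene(),
            circuit_transcriptional_autoreg(),
            circuit_post_transcriptional(),
            circuit_post_transcriptional(transcript_mode="separate"),
            circuit_post_transcriptional_hill(),
        ):
            assert set(np.unique(net.stoichiometry)) <= {-1, 0, 1}


class TestConfigLoading:
    CFG = """
species: [R, P]
reactions:
  - {name: tx, stoich: {R: 1}, rate: "k_R * D0"}
  - {name: tl, stoich: {P: 1}, rate: "k_P * R"}
  - {name: dR, stoich: {R: -1}, rate: "gamma_R * R"}
  - {name: dP, stoich: {P: -1}, rate: "gamma_P * P"}
parameters: {k_R: 1.0, k_P: 1.0, gamma_R: 0.1, gamma_P: 0.01}
initial_conditions: {D0: 1.0, R: 0, P: 0}
"""

    def test_roundtrip_matches_library_circuit(self, single_gene):
        net = network_from_config(self.CFG)
        np.testing.assert_array_equal(net.stoichiometry, single_gene.stoichiometry)
        x = np.array([7.0, 30.0])
        np.testing.assert_allclose(
            evaluate_propensities(net, x), evaluate_propensities(single_gene, x)
        )

    def test_unknown_species_in_stoich(self):
        bad = self.CFG.replace("stoich: {P: 1}", "stoich: {X: 1}")
        with pytest.raises(NetworkSpecError, match="X"):
            network_from_config(bad)
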