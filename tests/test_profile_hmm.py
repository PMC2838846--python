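import json
import math

import numpy as np
import pytest

from conftest import random_profile_hmm
from oracles import enum_bits, enumerate_glocal, enumerate_local

from kinomeprofiler.profile_hmm import (
    ProfileHMM,
    build_from_alignment,
    forward_bit_score,
    read_hmmer3,
    read_model,
    score_many,
    score_proteome,
    viterbi_bit_score,
    viterbi_hit,
    write_model,
)
from kinomeprofiler.proteome_io import ProteinRecord


def deterministic_null_model(L: int) -> ProfileHMM:
    """Match emissions equal to the null, deterministic M->M path."""
    t = np.zeros((L + 1, 7))
    t[:, 0] = 1.0  # M->M only
    t[:, 3] = 1.0
    t[:, 5] = 1.0
    null = np.full(20, 0.05)
    return ProfileHMM(
        name="null-match", length=L,
        match_emissions=np.tile(null, (L, 1)),
        insert_emissions=np.tile(null, (L + 1, 1)),
        transitions=t, null_model=null, alignment_mode="glocal",
    )


class TestModelValidation:
    def test_valid_random_models_pass(self):
        for L in (1, 2, 5):
            random_profile_hmm(L, seed=L).validate()

    def test_bad_emission_row_rejected(self):
        hmm = random_profile_hmm(3, seed=0)
        bad = hmm.match_emissions.copy()
        bad[1] = bad[1] / 2.0
        with pytest.raises(ValueError, match="match emission"):
            ProfileHMM(
                name="bad", length=3, match_emissions=bad,
                insert_emissions=hmm.insert_emissions, transitions=hmm.transitions,
                null_model=hmm.null_model,
            )

    def test_bad_transition_row_rejected(self):
        hmm = random_profile_hmm(2, seed=1)
        bad = hmm.transitions.copy()
        bad[1, 0] += 0.3
        with pytest.raises(ValueError, match="transition"):
            ProfileHMM(
                name="bad", length=2, match_emissions=hmm.match_emissions,
                insert_emissions=hmm.insert_emissions, transitions=bad,
                null_model=hmm.null_model,
            )


class TestScoringAgainstEnumeration:
    """Viterbi/forward DP must equal brute-force path enumeration."""

    @pytest.mark.parametrize("L", [1, 2, 3])
    @pytest.mark.parametrize("slen", [1, 2, 3, 5])
    def test_all_small_models_and_sequences(self, L, slen):
        rng = np.random.default_rng(L * 10 + slen)
        for rep in range(2):
            hmm = random_profile_hmm(L, seed=1000 * L + 10 * slen + rep)
            seq = "".join(rng.choice(list("ACDE"), size=slen))
            for mode, enum in (("glocal", enumerate_glocal), ("local", enumerate_local)):
                weights = enum(hmm, seq)
                assert viterbi_bit_score(hmm, seq, mode=mode).value == pytest.approx(
                    enum_bits(weights, max), abs=1e-6
                )
                assert forward_bit_score(hmm, seq, mode=mode).value == pytest.approx(
                    enum_bits(weights, sum), abs=1e-6
                )

    def test_sequences_with_ambiguity_codes_scored_at_null(self):
        hmm = random_profile_hmm(2, seed=7)
        weights = enumerate_local(hmm, "AXC")
        assert viterbi_bit_score(hmm, "AXC", mode="local").value == pytest.approx(
            enum_bits(weights, max), abs=1e-6
        )


class TestScoreProperties:
    def test_null_match_deterministic_model_scores_zero_glocal(self):
        hmm = deterministic_null_model(4)
        assert viterbi_bit_score(hmm, "MKVA", mode="glocal").value == pytest.approx(0.0)
        assert forward_bit_score(hmm, "MKVA", mode="glocal").value == pytest.approx(0.0)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(3)
        for rep in range(6):
            hmm = random_profile_hmm(int(rng.integers(1, 5)), seed=rep)
            seq = "".join(rng.choice(list("ACDEFGHIKL"), size=int(rng.integers(1, 12))))
            for mode in ("local", "glocal"):
                assert (forward_bit_score(hmm, seq, mode=mode).value
                        >= viterbi_bit_score(hmm, seq, mode=mode).value - 1e-9)

    def test_single_path_model_forward_equals_viterbi(self):
        hmm = deterministic_null_model(3)
        assert forward_bit_score(hmm, "MKV", mode="glocal").value == pytest.approx(
            viterbi_bit_score(hmm, "MKV", mode="glocal").value
        )

    def test_boosting_observed_residue_emission_never_lowers_viterbi(self):
        base = random_profile_hmm(3, seed=11)
        seq = "AAA"
        before = viterbi_bit_score(base, seq, mode="local").value
        me = base.match_emissions.copy()
        me[:, 0] *= 2.0
        me /= me.sum(axis=1, keepdims=True)
        boosted = ProfileHMM(
            name="boost", length=3, match_emissions=me,
            insert_emissions=base.insert_emissions, transitions=base.transitions,
            null_model=base.null_model,
        )
        after = viterbi_bit_score(boosted, seq, mode="local").value
        assert after >= before - 1e-9

    def test_local_score_invariant_under_null_flanks_by_convention(self):
        # flanks are free, so appending residues never lowers the local score,
        # and a flank that cannot beat the planted hit leaves it unchanged
        hmm = random_profile_hmm(3, seed=21)
        core = "ACD"
        s0 = viterbi_bit_score(hmm, core, mode="local").value
        flanked = viterbi_bit_score(hmm, "GG" + core + "GG", mode="local").value
        assert flanked >= s0 - 1e-9
        strong = deterministic_consensus_model("ACDEF")
        hit = viterbi_bit_score(strong, "ACDEF", mode="local").value
        hit_flanked = viterbi_bit_score(strong, "GGGACDEFGGG", mode="local").value
        assert hit_flanked == pytest.approx(hit, abs=1e-9)

    def test_long_sequences_stay_finite(self):
        hmm = random_profile_hmm(10, seed=5)
        seq = "".join(np.random.default_rng(0).choice(list("ACDEFGHIKL"), size=10_000))
        for fn in (viterbi_bit_score, forward_bit_score):
            for mode in ("local", "glocal"):
                assert math.isfinite(fn(hmm, seq, mode=mode).value)

    def test_batched_scoring_equals_per_sequence(self, group_library):
        rng = np.random.default_rng(9)
        prots = [
            ProteinRecord(id=f"p{i}", description="",
                          sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                                      size=int(rng.integers(5, 120)))))
            for i in range(25)
        ]
        single = np.array([score_many(group_library.models, p) for p in prots])
        batched = score_proteome(group_library.models, prots)
        np.testing.assert_allclose(batched, single, atol=1e-9)

    def test_empty_sequence_rejected(self):
        hmm = random_profile_hmm(2, seed=1)
        with pytest.raises(ValueError):
            viterbi_bit_score(hmm, "")


def deterministic_consensus_model(consensus: str) -> ProfileHMM:
    """Near-deterministic emissions on a consensus string (peak 0.99)."""
    from kinomeprofiler.proteome_io import AMINO_ACIDS

    L = len(consensus)
    me = np.full((L, 20), 0.01 / 19.0)
    for j, ch in enumerate(consensus):
        me[j, AMINO_ACIDS.index(ch)] = 0.99
    t = np.zeros((L + 1, 7))
    t[:, 0], t[:, 3], t[:, 5] = 1.0, 1.0, 1.0
    return ProfileHMM(
        name="cons", length=L, match_emissions=me,
        insert_emissions=np.full((L + 1, 20), 0.05),
        transitions=t, null_model=np.full(20, 0.05),
    )


class TestViterbiHit:
    def test_envelope_covers_planted_segment(self):
        strong = deterministic_consensus_model("ACDEFGHIKL")
        seq = "MMMMM" + "ACDEFGHIKL" + "WWWWW"
        score, start, end = viterbi_hit(strong, seq)
        assert score > 20
        assert (start, end) == (6, 15)

    def test_hit_score_matches_plain_local_viterbi(self):
        hmm = random_profile_hmm(4, seed=13)
        seq = "ACDEFGHIKLMNPQ"
        score, start, end = viterbi_hit(hmm, seq)
        assert score == pytest.approx(viterbi_bit_score(hmm, seq, mode="local").value)
        assert 1 <= start <= end <= len(seq)


class TestBuildFromAlignment:
    def test_identical_rows_give_modal_emissions(self):
        hmm = build_from_alignment(["ACDE"] * 4)
        assert hmm.length == 4
        for j, ch in enumerate("ACDE"):
            from kinomeprofiler.proteome_io import AMINO_ACIDS

            assert np.argmax(hmm.match_emissions[j]) == AMINO_ACIDS.index(ch)

    def test_all_gap_column_not_a_match_state(self):
        hmm = build_from_alignment(["A-C", "A-C", "A-C"])
        assert hmm.length == 2

    def test_emission_rows_sum_to_one(self):
        hmm = build_from_alignment(["ACDE", "AC-E", "GCDE", "AC-E"])
        np.testing.assert_allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(hmm.insert_emissions.sum(axis=1), 1.0, atol=1e-9)

    def test_half_gap_boundary_follows_rule(self):
        # gap fraction exactly 0.5 is NOT below the default rule -> insert column
        hmm = build_from_alignment(["AC", "A-"])
        assert hmm.length == 1

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_from_alignment([])
        with pytest.raises(ValueError, match="unequal"):
            build_from_alignment(["AC", "A"])


class TestModelIO:
    def test_json_round_trip_is_lossless(self, tmp_path):
        hmm = random_profile_hmm(5, seed=17)
        write_model(hmm, tmp_path / "m.json")
        back = read_model(tmp_path / "m.json")
        assert back.name == hmm.name and back.length == hmm.length
        np.testing.assert_allclose(back.match_emissions, hmm.match_emissions)
        np.testing.assert_allclose(back.insert_emissions, hmm.insert_emissions)
        np.testing.assert_allclose(back.transitions, hmm.transitions)
        np.testing.assert_allclose(back.null_model, hmm.null_model)

    def test_invalid_probability_rows_rejected_on_read(self, tmp_path):
        hmm = random_profile_hmm(2, seed=19)
        write_model(hmm, tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        doc["match_emissions"][0] = [0.025] * 20  # sums to 0.5
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="match emission"):
            read_model(tmp_path / "bad.json")

    def test_hmmer3_import_minimal_stanza(self, tmp_path):
        hmm = _write_minimal_hmmer3(tmp_path / "toy.hmm", L=2)
        warnings: list[str] = []
        imported = read_hmmer3(tmp_path / "toy.hmm", warnings=warnings)
        assert imported.length == 2
        assert imported.name == "toy"
        imported.validate()
        assert any("null" in w or "COMPO" in w for w in warnings)


def _write_minimal_hmmer3(path, L):
    from kinomeprofiler.proteome_io import AMINO_ACIDS

    uniform = " ".join(f"{math.log(20.0):.5f}" for _ in range(20))
    # transitions: mm mi md im ii dm dd as -ln(p)
    t_mid = "  0.40546  1.79176  1.79176  0.10536  2.30259  0.10536  2.30259"
    t_last = "  0.01005  4.60517  *  0.10536  2.30259  0.00000  *"
    lines = [
        "HMMER3/f [toy]",
        "NAME  toy",
        f"LENG  {L}",
        "ALPH  amino",
        "HMM          " + "  ".join(AMINO_ACIDS),
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
        f"  {uniform}",  # insert 0 emissions
        t_mid,  # node 0 transitions
    ]
    for k in range(1, L + 1):
        lines.append(f"      {k}  {uniform}")
        lines.append(f"  {uniform}")
        lines.append(t_last if k == L else t_mid)
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
    return path
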