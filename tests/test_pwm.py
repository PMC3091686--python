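import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tc2tf.io_formats import PwmRecord
from tc2tf.pwm import (best_score, build_hit_table, build_logodds, encode,
                       permutation_pvalue)
from tc2tf.simulate import generate_pwm_library, reverse_complement

dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


def brute_force_best(seq: str, lo) -> tuple[float, int, str]:
    """Independent double-loop scorer over both strands (pure Python)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = lo.length
    W = lo.weights
    best = (-np.inf, None, None)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s) - L + 1):
            window = s[i:i + L]
            if "N" in window:
                continue
            score = sum(W[idx[ch], j] for j, ch in enumerate(window))
            pos = i if strand == "+" else len(seq) - L - i
            cand = (score, pos, strand)
            if (score > best[0] + 1e-9 or
                (abs(score - best[0]) <= 1e-9 and
                 (pos, strand) < (best[1], best[2]))):
                best = cand
    return best


class TestBuildLogodds:
    def test_uniform_counts_uniform_background_all_zero(self):
        pwm = PwmRecord("u", counts=np.full((4, 3), 25.0))
        lo = build_logodds(pwm, pseudocount=1.0)
        np.testing.assert_allclose(lo.weights, 0.0, atol=1e-12)

    def test_hand_computed_weights(self):
        """A=98 and zero elsewhere: w_A = log2(98.25/24.75), w_C =
        log2(0.25/24.75)."""
        pwm = PwmRecord("h", counts=np.array([[98.0], [0.0], [0.0], [0.0]]))
        lo = build_logodds(pwm, pseudocount=1.0)
        assert lo.weights[0, 0] == pytest.approx(np.log2(98.25 / 24.75))
        assert lo.weights[1, 0] == pytest.approx(np.log2(0.25 / 24.75))

    def test_pseudocount_keeps_weights_finite(self):
        rng = np.random.default_rng(0)
        pwm = PwmRecord("r", counts=rng.integers(0, 100, (4, 8)) * 1.0
                        + np.eye(4, 8))
        lo = build_logodds(pwm)
        assert np.isfinite(lo.weights).all()

    def test_zero_background_rejected(self):
        pwm = PwmRecord("z", counts=np.ones((4, 2)))
        with pytest.raises(ValueError, match="background"):
            build_logodds(pwm, background=(0.5, 0.5, 0.0, 0.0))


class TestBestScore:
    def _two_pos_motif(self):
        # weights: position 1 favors A (+1, else -1), position 2 favors C
        counts = np.array([[97.0, 1.0], [1.0, 97.0], [1.0, 1.0], [1.0, 1.0]])
        pwm = PwmRecord("ac", counts=counts)
        return build_logodds(pwm)

    def test_forward_hit_found_at_position(self):
        lo = self._two_pos_motif()
        score, pos, strand = best_score("GACG", lo)
        assert (pos, strand) == (1, "+")
        bf = brute_force_best("GACG", lo)
        assert score == pytest.approx(bf[0])

    def test_sequence_equal_to_motif_length(self):
        lo = self._two_pos_motif()
        score, pos, strand = best_score("AC", lo)
        assert pos == 0

    def test_too_short_sequence_rejected(self):
        lo = self._two_pos_motif()
        with pytest.raises(ValueError, match="shorter"):
            best_score("A", lo)

    def test_case_insensitive(self):
        lo = self._two_pos_motif()
        assert best_score("gacg", lo)[0] == best_score("GACG", lo)[0]

    def test_n_window_never_wins(self):
        lo = self._two_pos_motif()
        # the only N-free window is GG; it must win despite its poor score
        score, pos, strand = best_score("NNGG", lo)
        assert pos == 2 and score < 0
        assert score > -1e20  # an N window would sit at the sentinel floor

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, st.integers(0, 3))
    def test_strand_symmetry(self, seq, seed):
        lib = generate_pwm_library(1, length_range=(5, 8), seed=seed)
        lo = build_logodds(lib[0])
        if len(seq) < lo.length:
            return
        assert best_score(seq, lo)[0] == pytest.approx(
            best_score(reverse_complement(seq), lo)[0], abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, st.integers(0, 5))
    def test_matches_bruteforce_oracle(self, seq, seed):
        lib = generate_pwm_library(1, length_range=(4, 6), seed=seed)
        lo = build_logodds(lib[0])
        if len(seq) < lo.length:
            return
        score, pos, strand = best_score(seq, lo)
        b_score, b_pos, b_strand = brute_force_best(seq, lo)
        assert score == pytest.approx(b_score, abs=1e-9)


class TestPermutationPvalue:
    def test_homopolymer_gives_p_one(self):
        lib = generate_pwm_library(1, length_range=(4, 4), seed=1)
        lo = build_logodds(lib[0])
        res = permutation_pvalue("A" * 50, lo, n_perm=50, seed=0)
        assert res["perm_p"] == 1.0

    def test_minimum_p_is_add_one_bound(self):
        """A planted perfect site in background: p bottoms out at 1/(N+1)."""
        lib = generate_pwm_library(1, length_range=(8, 8),
                                   information_content_range=(2.0, 2.0),
                                   seed=2)
        lo = build_logodds(lib[0])
        consensus = "".join("ACGT"[i] for i in lo.weights.argmax(axis=0))
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300)) + consensus
        res = permutation_pvalue(seq, lo, n_perm=100, seed=4)
        assert res["perm_p"] >= 1.0 / 101.0  # add-one lower bound
        assert res["perm_p"] < 0.05
        assert res["best_position"] == 300 and res["best_strand"] == "+"

    def test_deterministic_under_seed(self):
        lib = generate_pwm_library(1, seed=5)
        lo = build_logodds(lib[0])
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        a = permutation_pvalue(seq, lo, n_perm=80, seed=7)
        b = permutation_pvalue(seq, lo, n_perm=80, seed=7)
        assert a == b

    def test_dinucleotide_shuffle_preserves_composition(self):
        from tc2tf.pwm import _dinucleotide_shuffle, encode
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        codes = encode(seq)
        shuffled = _dinucleotide_shuffle(codes, rng)

        def dinucs(c):
            from collections import Counter
            return Counter(zip(c[:-1].tolist(), c[1:].tolist()))
        assert dinucs(shuffled) == dinucs(codes)


class TestHitTable:
    def _setup(self):
        lib = generate_pwm_library(2, length_range=(6, 6), seed=9)
        rng = np.random.default_rng(10)
        proms = {f"g{i}": "".join(rng.choice(list("ACGT"), size=150))
                 for i in range(6)}
        return proms, lib

    def test_alpha_zero_gives_no_hits(self):
        proms, lib = self._setup()
        hits, scan = build_hit_table(proms, lib, alpha=0.0, n_perm=20, seed=0)
        assert not hits.to_numpy().any()

    def test_alpha_one_hits_everything_except_p_equal_one(self):
        proms, lib = self._setup()
        hits, scan = build_hit_table(proms, lib, alpha=1.0, n_perm=20, seed=0)
        expect = (scan["perm_p"] < 1.0).to_numpy()
        assert (scan["significant"].to_numpy() == expect).all()

    def test_empty_motif_list_rejected(self):
        proms, _ = self._setup()
        with pytest.raises(ValueError, match="empty motif"):
            build_hit_table(proms, [], n_perm=10)

    def test_planted_set_has_higher_hit_rate(self):
        from tc2tf.simulate import PlantingRule, generate_promoters
        lib = generate_pwm_library(1, length_range=(8, 8),
                                   information_content_range=(1.8, 2.0),
                                   seed=11)
        genes = [f"g{i}" for i in range(40)]
        plan = [PlantingRule(lib[0].motif_id, frozenset(genes[:20]), 1.0)]
        proms, _ = generate_promoters(genes, lib, plan, length=400, seed=12)
        hits, _ = build_hit_table(proms, lib, alpha=0.1, n_perm=60, seed=13)
        planted_rate = hits.iloc[:20, 0].mean()
        bg_rate = hits.iloc[20:, 0].mean()
        assert planted_rate > bg_rate
        assert planted_rate > 0.8
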