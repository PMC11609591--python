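"""Generators with known ground truth: random sequences, structures, samples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from endloop.errors import DomainError
from endloop.folding import parse_dotbracket
from endloop.exterior_loop import exterior_summary
from endloop.synthetic_data import (
    RandomSeqSpec,
    SyntheticStructureSpec,
    generate_random_sequences,
    generate_structure,
    sample_gaussian,
    write_fasta,
    write_fold_file,
)


class TestRandomSequences:
    def test_published_control_dimensions(self):
        seqs = generate_random_sequences(RandomSeqSpec(count=50, length=1600, seed=3))
        assert len(seqs) == 50
        assert all(len(s) == 1600 for s in seqs)
        assert all(set(s) <= set("ACGU") for s in seqs)

    def test_zero_count_gives_empty_list(self):
        assert generate_random_sequences(RandomSeqSpec(count=0, length=10)) == []

    def test_same_seed_byte_identical(self):
        spec = RandomSeqSpec(count=5, length=300, seed=11)
        assert generate_random_sequences(spec) == generate_random_sequences(spec)

    def test_different_seeds_differ(self):
        a = generate_random_sequences(RandomSeqSpec(count=1, length=300, seed=1))
        b = generate_random_sequences(RandomSeqSpec(count=1, length=300, seed=2))
        assert a != b

    def test_uniform_composition_chi_square(self):
        # pooled base counts of 100 x 10 kb must be consistent with uniformity
        seqs = generate_random_sequences(
            RandomSeqSpec(count=100, length=10000, seed=1)
        )
        pooled = "".join(seqs)
        counts = [pooled.count(b) for b in "ACGU"]
        chi2 = sum((c - len(pooled) / 4) ** 2 / (len(pooled) / 4) for c in counts)
        p = sps.chi2.sf(chi2, df=3)
        assert p > 0.01

    def test_invalid_probs_rejected(self):
        with pytest.raises(DomainError):
            RandomSeqSpec(count=1, length=10, base_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(DomainError):
            RandomSeqSpec(count=-1, length=10)


class TestGenerateStructure:
    def test_inspectable_small_example(self):
        st_ = generate_structure(
            SyntheticStructureSpec(ext_unpaired=4, top_helices=1, helix_len=2,
                                   hairpin_len=3, seed=5)
        )
        assert st_.structure.count("(") == 2
        assert st_.structure.count(".") == 4 + 3
        assert st_.link_count == 4 + 2 * 1 - 1
        # exterior unpaired count read off the emitted string
        db = st_.structure
        depth = 0
        ext_dots = 0
        for ch in db:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif depth == 0:
                ext_dots += 1
        assert ext_dots == 4

    def test_single_helix_spanning_termini(self):
        st_ = generate_structure(SyntheticStructureSpec(ext_unpaired=0, top_helices=1))
        assert st_.structure.startswith("(") and st_.structure.endswith(")")
        assert st_.link_count == 1

    def test_all_unpaired_chain(self):
        st_ = generate_structure(SyntheticStructureSpec(ext_unpaired=5, top_helices=0))
        assert st_.structure == "....."
        assert st_.link_count == 4

    def test_infeasible_spec_rejected(self):
        with pytest.raises(DomainError):
            SyntheticStructureSpec(ext_unpaired=0, top_helices=0)

    @settings(max_examples=60, deadline=None)
    @given(
        u=st.integers(min_value=0, max_value=40),
        h=st.integers(min_value=0, max_value=6),
        helix_len=st.integers(min_value=1, max_value=6),
        hairpin_len=st.integers(min_value=3, max_value=8),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_output_parses_and_matches_ground_truth(self, u, h, helix_len,
                                                    hairpin_len, seed):
        """The module's reason to exist: emitted structures parse cleanly and
        the summary link count equals the construction's ground truth."""
        if u + h == 0:
            return
        st_ = generate_structure(
            SyntheticStructureSpec(ext_unpaired=u, top_helices=h,
                                   helix_len=helix_len, hairpin_len=hairpin_len,
                                   seed=seed)
        )
        structure = parse_dotbracket(f"{st_.sequence}\n{st_.structure}")
        summary = exterior_summary(structure)
        assert summary.ext_unpaired == u
        assert summary.top_helices == h
        assert summary.link_count == st_.link_count

    def test_paired_positions_watson_crick(self):
        st_ = generate_structure(
            SyntheticStructureSpec(ext_unpaired=6, top_helices=3, helix_len=4, seed=9)
        )
        structure = parse_dotbracket(f"{st_.sequence}\n{st_.structure}")
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        for i, j in enumerate(structure.pairs, start=1):
            if j > i:
                assert (structure.sequence[i - 1], structure.sequence[j - 1]) in wc


class TestSampleGaussian:
    def test_mean_recovered_within_three_standard_errors(self):
        vals = sample_gaussian(10000, center=9.0, width_w=6.03, seed=7)
        sigma = 6.03 / np.sqrt(2)
        se = sigma / np.sqrt(10000)
        assert abs(vals.mean() - 9.0) < 3 * se + 0.05  # slack for truncation at 0

    def test_single_draw_nonnegative(self):
        vals = sample_gaussian(1, center=2.0, width_w=1.0, seed=0)
        assert vals.shape == (1,)
        assert vals[0] >= 0

    def test_vanishing_width_collapses_to_center(self):
        vals = sample_gaussian(100, center=5.0, width_w=1e-9, seed=1)
        assert np.allclose(vals, 5.0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DomainError):
            sample_gaussian(10, center=5.0, width_w=0.0)

    def test_all_values_nonnegative(self):
        vals = sample_gaussian(5000, center=1.0, width_w=3.0, seed=2)
        assert (vals >= 0).all()

    def test_reproducible(self):
        a = sample_gaussian(100, 9.0, 6.0, seed=5)
        b = sample_gaussian(100, 9.0, 6.0, seed=5)
        assert np.array_equal(a, b)


def test_plain_text_writers_round_trip(tmp_path):
    seqs = generate_random_sequences(RandomSeqSpec(count=3, length=150, seed=2))
    fasta = tmp_path / "r.fa"
    write_fasta(seqs, fasta)
    from endloop.sequence_io import read_sequences

    back = read_sequences(fasta, "fasta")
    assert [r.sequence for r in back] == seqs

    structs = [
        generate_structure(SyntheticStructureSpec(ext_unpaired=5, top_helices=2, seed=s))
        for s in range(3)
    ]
    fold = tmp_path / "s.fold"
    write_fold_file(structs, fold)
    from endloop.folding import read_fold_file

    parsed = list(read_fold_file(fold.read_text()))
    assert len(parsed) == 3
    assert [p[1].sequence for p in parsed] == [s.sequence for s in structs]
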