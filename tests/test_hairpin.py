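"""Folding engine vs exhaustive oracle, duplex geometry, precision,
feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircurate.core import MatureRecord, PrecursorRecord, revcomp_rna
from mircurate.fixtures import FixtureConfig, plant_hairpin
from mircurate.hairpin import (
    DEFAULT_REGISTRY,
    FoldParams,
    amfe,
    extract_duplex,
    extract_features,
    fold_hairpin,
    precision_of_processing,
    structure_from_dotbracket,
)
from mircurate.srna import ReadStack

from oracles import brute_force_min_energy


class TestFold:
    def test_perfect_toy_hairpin(self):
        st = fold_hairpin("GGGAAACCC")
        assert st.dotbracket == "(((...)))"
        assert st.energy == -9.0

    def test_unpairable_sequence(self):
        st = fold_hairpin("AAAAAA")
        assert st.dotbracket == "......"
        assert st.energy == 0.0

    def test_invalid_characters_error(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            fold_hairpin("ACGXACGU")

    def test_t_input_accepted(self):
        assert fold_hairpin("GGGAAACCC".replace("G", "G")).energy == fold_hairpin(
            "GGGAAACCC"
        ).energy

    @pytest.mark.parametrize("seed", range(40))
    def test_energy_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        st = fold_hairpin(seq)
        assert st.energy == brute_force_min_energy(seq)

    def test_energy_consistent_with_pair_table(self):
        rng = np.random.default_rng(123)
        params = FoldParams()
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=40))
            st = fold_hairpin(seq, params)
            recomputed = sum(
                params.weight(seq[i], seq[j]) for i, j in st.pairs.items() if i < j
            )
            assert recomputed == st.energy

    def test_min_loop_respected(self):
        st = fold_hairpin("GGGGAAACCCC", FoldParams(min_loop=5))
        assert all(j - i - 1 >= 5 for i, j in st.pairs.items() if i < j)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=30))
    def test_structure_invariants_hold_for_any_sequence(self, seq):
        """Energy is never positive, equals the pair-table sum, brackets
        balance, and every loop respects the minimum size."""
        params = FoldParams()
        stx = fold_hairpin(seq, params)
        assert stx.energy <= 0
        assert stx.dotbracket.count("(") == stx.dotbracket.count(")")
        recomputed = sum(
            params.weight(seq[i], seq[j]) for i, j in stx.pairs.items() if i < j
        )
        assert recomputed == stx.energy
        assert all(j - i - 1 >= params.min_loop for i, j in stx.pairs.items() if i < j)

    def test_dotbracket_input_path(self):
        st = structure_from_dotbracket("(((...)))", seq="GGGAAACCC")
        assert st.energy == -9.0 and st.pairs[0] == 8

    def test_unbalanced_dotbracket_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            structure_from_dotbracket("((...)")


class TestAmfe:
    @pytest.mark.parametrize(
        "energy,length,expected", [(-40, 100, -40.0), (-9, 9, -100.0), (0, 50, 0.0)]
    )
    def test_formula(self, energy, length, expected):
        assert amfe(energy, length) == expected

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            amfe(-10, 0)

    def test_planted_hairpin_family_scale_consistency(self):
        """Embedding the same perfect stem in a longer context never makes
        AMFE more negative than the bare hairpin's."""
        stem = "GCGGAUGCGGAUGCGGAUGCG"
        bare = stem + "AAAA" + revcomp_rna(stem)
        st = fold_hairpin(bare)
        base_amfe = amfe(st.energy, len(bare))
        for pad in ("A" * 10, "A" * 30):
            padded = pad + bare + pad
            stp = fold_hairpin(padded)
            assert amfe(stp.energy, len(padded)) >= base_amfe


def _planted(seed=5, mature_len=21):
    rng = np.random.default_rng(seed)
    cfg = FixtureConfig(seed=seed, mature_len=mature_len)
    seq, m0, s0, sl = plant_hairpin(rng, cfg)
    mature = MatureRecord("m", "unknown", m0, mature_len, seq[m0 : m0 + mature_len])
    return seq, mature, (s0, sl)


class TestDuplex:
    @pytest.mark.parametrize("seed", range(10))
    def test_perfect_stem_geometry(self, seed):
        """s + loop + revcomp(s) fixtures: 0 mismatches, no bulges, 2/2
        3' overhangs, star at the planted partner position."""
        seq, mature, star = _planted(seed)
        st = fold_hairpin(seq)
        d = extract_duplex(st, mature)
        assert d.mismatches == 0
        assert d.asym_bulge_nt == 0
        assert (d.overhang_3p_5arm, d.overhang_3p_3arm) == (2, 2)
        assert (d.star_offset, d.star_length) == star

    def test_engineered_asymmetric_bulge(self):
        # 10-pair stem; the star strand carries a 2-nt asymmetric bulge
        db = "." + "(" * 10 + "." * 5 + ")" * 5 + ".." + ")" * 5 + "."
        st = structure_from_dotbracket(db, energy=-30.0)
        mature = MatureRecord("m", "5p", 1, 12, "A" * 12)
        d = extract_duplex(st, mature)
        assert d.asym_bulge_nt == 2
        assert d.mismatches == 0

    def test_loop_spanning_mature_errors(self):
        seq, _, _ = _planted(3)
        st = fold_hairpin(seq)
        n = len(seq)
        loop_mature = MatureRecord(
            "m", "unknown", n // 2 - 10, 21, seq[n // 2 - 10 : n // 2 + 11]
        )
        with pytest.raises(ValueError, match="loop-spanning"):
            extract_duplex(st, loop_mature)

    def test_3p_arm_mature_symmetric(self):
        """A mature planted on the 3' arm yields the mirror-image duplex."""
        seq, mature5, star = _planted(8)
        st = fold_hairpin(seq)
        star_mature = MatureRecord(
            "m*", "unknown", star[0], star[1], seq[star[0] : star[0] + star[1]]
        )
        d = extract_duplex(st, star_mature)
        assert d.mismatches == 0
        assert (d.overhang_3p_5arm, d.overhang_3p_3arm) == (2, 2)


def _stack(entries):
    return ReadStack(precursor_id="p", precursor_length=120, entries=entries)


class TestPrecision:
    mature = MatureRecord("m", "5p", 10, 21, "A" * 21)

    def test_count_ratio(self):
        st = _stack([(10, 21, 9, "s0"), (50, 22, 1, "s0")])
        assert precision_of_processing(st, [self.mature]) == 0.9

    def test_star_reads_count_as_precise(self):
        st = _stack([(60, 21, 5, "s0")])
        assert precision_of_processing(st, [self.mature], star=(60, 21)) == 1.0

    def test_tolerance_semantics(self):
        st = _stack([(11, 21, 1, "s0")])  # both ends shifted by +1
        assert precision_of_processing(st, [self.mature], tol=0) == 0.0
        assert precision_of_processing(st, [self.mature], tol=1) == 1.0

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError, match="no read support"):
            precision_of_processing(_stack([]), [self.mature])

    @pytest.mark.parametrize("p", [0.5, 0.75, 0.95])
    def test_recovers_planted_precision(self, p):
        """Simulated stacks at depth 1000 recover the planted precision
        within 3 binomial standard errors."""
        from mircurate.fixtures import generate_bundle
        from mircurate.srna import build_read_stack

        cfg = FixtureConfig(
            seed=11, n_true=2, n_decoys=0, depth=1000, precision=p,
            isoform_rates={}, n_samples=1, arm_switch_fraction=0.0,
        )
        bundle = generate_bundle(cfg)
        for truth, rec in zip(bundle.true_loci(), bundle.records()):
            stack = build_read_stack(bundle.reads, rec)
            est = precision_of_processing(
                stack, rec.matures, star=(truth.star_offset, truth.star_len)
            )
            se = (p * (1 - p) / stack.total_count) ** 0.5
            assert abs(est - p) <= 3 * se


class TestFeatures:
    def test_gc_content(self):
        rec = PrecursorRecord(id="p", sequence="GGGGCCCC", sources={"db"})
        st = fold_hairpin(rec.sequence)
        feats = extract_features(rec, st)
        assert feats["gc_content"] == 1.0

    def test_paired_fraction_from_dotbracket(self):
        rec = PrecursorRecord(id="p", sequence="GGGAAACCC", sources={"db"})
        st = structure_from_dotbracket("(((...)))", seq=rec.sequence)
        feats = extract_features(rec, st)
        assert feats["paired_fraction"] == pytest.approx(6 / 9)

    def test_registry_order_is_deterministic(self):
        seq_a, mat_a, _ = _planted(1)
        seq_b, mat_b, _ = _planted(2)
        ra = PrecursorRecord(id="a", sequence=seq_a, sources={"db"}, matures=[mat_a])
        rb = PrecursorRecord(id="b", sequence=seq_b, sources={"db"}, matures=[mat_b])
        fa = extract_features(ra, fold_hairpin(seq_a))
        fb = extract_features(rb, fold_hairpin(seq_b))
        assert list(fa.index) == list(fb.index) == DEFAULT_REGISTRY.names()
        assert np.isfinite(fa.to_numpy()).all() and np.isfinite(fb.to_numpy()).all()

    def test_kmer_frequencies_normalized(self):
        seq, mature, _ = _planted(4)
        rec = PrecursorRecord(id="p", sequence=seq, sources={"db"}, matures=[mature])
        feats = extract_features(rec, fold_hairpin(seq))
        for k, n_kmers in ((1, 4), (2, 16), (3, 64)):
            cols = [c for c in feats.index if c.startswith("freq_") and len(c) == 5 + k]
            assert len(cols) == n_kmers
            assert feats[cols].sum() == pytest.approx(1.0)
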