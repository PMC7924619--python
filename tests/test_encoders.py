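"""Dimension contracts and numerical oracles for the five encoders."""

import numpy as np
import pytest

from pupfuse.alphabet import AA_ORDER, AA_TO_COL
from pupfuse.encoders import (AAIndexSet, encode_aai, encode_binary,
                              encode_cksaap, encode_dataset, encode_pbcksaap,
                              encode_tpc)
from pupfuse.pssm_profiles import WindowProfile, pseudo_profile
from pupfuse.seq_io import Dataset, PeptideWindow

from conftest import random_window


def homopolymer(res, w=57):
    chars = [res] * w
    chars[(w - 1) // 2] = "K"
    return PeptideWindow("".join(chars))


class TestDimensionContracts:
    @pytest.mark.parametrize("w", range(25, 62, 8))
    @pytest.mark.parametrize("k_max", [0, 2, 4])
    def test_all_encoders(self, rng, w, k_max):
        win = random_window(rng, w=w)
        idx = AAIndexSet.default()
        assert len(encode_binary(win).values) == 20 * w
        assert len(encode_aai(win, idx).values) == w * 15
        assert len(encode_tpc(win).values) == 8000
        assert len(encode_cksaap(win, k_max).values) == 400 * (k_max + 1)
        prof = pseudo_profile(win)
        assert len(encode_pbcksaap(win, prof, k_max).values) == 400 * (k_max + 1)

    def test_defaults_match_published_dimensions(self, rng):
        win = random_window(rng, w=57)
        assert len(encode_binary(win).values) == 1140
        assert len(encode_aai(win).values) == 855
        assert len(encode_tpc(win).values) == 8000
        assert len(encode_cksaap(win).values) == 2000
        assert len(encode_pbcksaap(win, pseudo_profile(win)).values) == 2000


class TestBinary:
    def test_homopolymer_ones_in_A_columns(self):
        fv = encode_binary(homopolymer("A"))
        assert fv.values.sum() == 57
        on = np.flatnonzero(fv.values)
        cols = on % 20
        assert set(cols) == {AA_TO_COL["A"], AA_TO_COL["K"]}

    def test_leading_pads_give_zero_block(self):
        win = random_window(np.random.default_rng(0), w=57, pad_left=28)
        fv = encode_binary(win)
        assert np.all(fv.values[: 28 * 20] == 0)

    def test_names_align_with_values(self, rng):
        win = random_window(rng, w=9)
        fv = encode_binary(win)
        for t, res in enumerate(win.residues):
            if res in AA_ORDER:
                name = f"Binary|pos={t - 4:+d}|{res}"
                assert fv.values[fv.names.index(name)] == 1.0


class TestAAI:
    def test_zero_scales_give_zero_vector(self, rng):
        idx = AAIndexSet(ids=[f"Z{i}" for i in range(15)], values=np.zeros((15, 20)))
        assert np.all(encode_aai(random_window(rng), idx).values == 0)

    def test_single_indicator_scale_positional_bookkeeping(self):
        values = np.zeros((15, 20))
        values[3, AA_TO_COL["A"]] = 1.0
        idx = AAIndexSet(ids=[f"S{i}" for i in range(15)], values=values)
        fv = encode_aai(homopolymer("A"), idx)
        on = np.flatnonzero(fv.values)
        # 56 'A' positions (center is K), each hitting slot 3 of its block
        assert len(on) == 56
        assert np.all(on % 15 == 3)

    def test_default_set_loads_15_complete_scales(self):
        idx = AAIndexSet.default()
        assert len(idx) == 15
        assert idx.values.shape == (15, 20)
        assert np.isfinite(idx.values).all()


class TestTPC:
    def test_homopolymer_single_support(self):
        fv = encode_tpc(homopolymer("A", w=5))
        # window AAKAA: standard triples AAK, AKA, KAA
        nz = {fv.names[i]: fv.values[i] for i in np.flatnonzero(fv.values)}
        assert nz == {"TPC|AAK": 1 / 3, "TPC|AKA": 1 / 3, "TPC|KAA": 1 / 3}

    def test_pure_homopolymer_is_delta(self):
        win = PeptideWindow("A" * 28 + "K" + "A" * 28)
        fv = encode_tpc(win)
        assert fv.values.sum() == pytest.approx(1.0)

    def test_repeat_pattern_matches_sliding_counter_oracle(self):
        seq = ("ACD" * 19)[:57]
        chars = list(seq)
        chars[28] = "K"
        win = PeptideWindow("".join(chars))
        fv = encode_tpc(win)
        # brute-force sliding triple counter
        counts = {}
        for t in range(55):
            tri = win.residues[t:t + 3]
            counts[tri] = counts.get(tri, 0) + 1
        for name, v in zip(fv.names, fv.values):
            tri = name.split("|")[1]
            assert v == pytest.approx(counts.get(tri, 0) / 55)

    def test_pad_free_window_sums_to_one(self, rng):
        fv = encode_tpc(random_window(rng, w=57))
        assert fv.values.sum() == pytest.approx(1.0)

    def test_bounds(self, rng):
        fv = encode_tpc(random_window(rng, w=25, pad_left=5))
        assert np.all(fv.values >= 0) and np.all(fv.values <= 1)


class TestCKSAAP:
    def test_homopolymer_oracle(self):
        fv = encode_cksaap(homopolymer("A"), k_max=4)
        vals = dict(zip(fv.names, fv.values))
        for k in range(5):
            for a in AA_ORDER:
                for b in AA_ORDER:
                    v = vals[f"CKSAAP|k={k}|{a}-{b}"]
                    if a == b == "A":
                        # center K removes 2 (A,A) pairs at every k
                        assert v == pytest.approx((56 - k - 2) / (56 - k))
                    elif "K" in (a, b) and "A" in (a, b):
                        assert v == pytest.approx(1 / (56 - k))
                    elif (a, b) != ("K", "K"):
                        assert v == 0

    def test_all_pad_except_center_is_zero(self):
        win = PeptideWindow("-" * 28 + "K" + "-" * 28)
        assert np.all(encode_cksaap(win).values == 0)

    def test_k_max_too_large(self):
        with pytest.raises(ValueError):
            encode_cksaap(PeptideWindow("AKA"), k_max=2)

    def test_order_sensitivity(self):
        """Reversing an asymmetric pad-free window changes the encoding."""
        win = PeptideWindow("AC" * 14 + "K" + "DE" * 14)
        rev = PeptideWindow(win.residues[::-1])
        assert not np.array_equal(encode_cksaap(win).values,
                                  encode_cksaap(rev).values)

    def test_bounds(self, rng):
        for _ in range(10):
            fv = encode_cksaap(random_window(rng, w=31, pad_left=3))
            assert np.all(fv.values >= 0) and np.all(fv.values <= 1)


def brute_force_pbcksaap(P, k_max):
    """Triple-loop oracle over (k, a, b, t) for the clamped min-pair sum."""
    w = P.shape[0]
    out = np.zeros(400 * (k_max + 1))
    for k in range(k_max + 1):
        for a in range(20):
            for b in range(20):
                s = 0.0
                for t in range(w - k - 1):
                    s += max(min(P[t, a], P[t + k + 1, b]), 0.0)
                out[400 * k + a * 20 + b] = s / (w - k - 1)
    return out


class TestPbCKSAAP:
    def test_all_zero_profile(self, rng):
        win = random_window(rng, w=9)
        prof = WindowProfile(np.zeros((9, 20)))
        assert np.all(encode_pbcksaap(win, prof, 2).values == 0)

    def test_all_negative_profile_clamped_to_zero(self, rng):
        win = random_window(rng, w=9)
        prof = WindowProfile(-np.abs(rng.normal(size=(9, 20))) - 0.1)
        assert np.all(encode_pbcksaap(win, prof, 2).values == 0)

    def test_hand_case_w5_k0(self):
        win = PeptideWindow("AAKAA")
        P = np.zeros((5, 20))
        P[0, AA_TO_COL["A"]] = 3
        P[1, AA_TO_COL["R"]] = 2
        fv = encode_pbcksaap(win, WindowProfile(P), k_max=0)
        vals = dict(zip(fv.names, fv.values))
        assert vals["pbCKSAAP|k=0|A-R"] == pytest.approx(2 / 4)
        assert sum(v != 0 for v in fv.values) == 1

    def test_fuzzed_against_triple_loop_oracle(self, rng):
        """Vectorized encoder equals the brute-force sum on random input."""
        for _ in range(25):
            w = int(rng.choice([5, 7, 9, 11]))
            k_max = int(rng.integers(0, min(4, w - 2) + 1))
            win = random_window(rng, w=w)
            P = rng.integers(-6, 7, size=(w, 20)).astype(float)
            fv = encode_pbcksaap(win, WindowProfile(P), k_max)
            assert np.allclose(fv.values, brute_force_pbcksaap(P, k_max))

    def test_one_hot_pseudo_profile_reduces_to_cksaap(self, rng):
        """Cross-encoder oracle: profile one-hot at scale 1 == CKSAAP."""
        for pad in (0, 4):
            win = random_window(rng, w=31, pad_left=pad)
            pb = encode_pbcksaap(win, pseudo_profile(win, 1.0), k_max=4)
            ck = encode_cksaap(win, k_max=4)
            assert np.allclose(pb.values, ck.values)

    def test_size_mismatch(self, rng):
        win = random_window(rng, w=9)
        with pytest.raises(ValueError, match="rows"):
            encode_pbcksaap(win, WindowProfile(np.zeros((7, 20))), 2)


class TestEncodeDataset:
    def test_binary_matrix_shape(self, small_planted_dataset):
        m = encode_dataset(small_planted_dataset, "Binary")
        assert m.X.shape == (120, 1140)
        assert list(m.labels) == [1] * 60 + [0] * 60

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            encode_dataset(Dataset(windows=[]), "Binary")

    def test_column_consistency_with_per_window_encoder(self, small_planted_dataset):
        m = encode_dataset(small_planted_dataset, "CKSAAP")
        col = m.names.index("CKSAAP|k=0|A-A")
        for i in (0, 7, 119):
            fv = encode_cksaap(small_planted_dataset.windows[i])
            assert m.X[i, col] == fv.values[col]

    def test_pbcksaap_requires_profiles_or_fallback(self, small_planted_dataset):
        with pytest.raises(ValueError, match="pseudo"):
            encode_dataset(small_planted_dataset, "pbCKSAAP")
        m = encode_dataset(small_planted_dataset, "pbCKSAAP", allow_pseudo=True)
        assert m.X.shape == (120, 2000)
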