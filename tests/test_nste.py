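"""Ordinal symbolization, transfer entropy, NSTE direction recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gammasurge.core import BANDS
from gammasurge.nste import (
    NSTEMatrix,
    NSTEParams,
    conditional_entropy,
    directed_band_matrix,
    ff_fb_summary,
    nste,
    ordinal_symbolize,
    symbolic_te,
)
from gammasurge.synth import DirLink, SessionSpec, StageSpec, gen_directed_pair, gen_session

FS = 512.0


def brute_force_te(x, y, delta, a):
    """Triple-histogram TE evaluated with explicit dictionaries."""
    from collections import Counter

    triples = Counter()
    pairs_yp_x = Counter()
    pairs_yf_yp = Counter()
    singles_yp = Counter()
    n = 0
    for t in range(len(y) - delta):
        yf, yp, xs = y[t + delta], y[t], x[t]
        triples[(yf, yp, xs)] += 1
        pairs_yp_x[(yp, xs)] += 1
        pairs_yf_yp[(yf, yp)] += 1
        singles_yp[yp] += 1
        n += 1
    te = 0.0
    for (yf, yp, xs), c in triples.items():
        p_joint = c / n
        p_cond_full = c / pairs_yp_x[(yp, xs)]
        p_cond_past = pairs_yf_yp[(yf, yp)] / singles_yp[yp]
        te += p_joint * math.log2(p_cond_full / p_cond_past)
    return te


class TestOrdinalSymbolize:
    def test_increasing_series_identity_pattern(self):
        sym = ordinal_symbolize(np.arange(20.0), d=3, tau=1)
        assert np.all(sym == 0)  # (0,1,2) is the first pattern lexicographically

    def test_hand_enumerated_patterns(self):
        # (3,1,2): ranks (2,0,1) -> lexicographic index 4
        # (1,2,5): ranks (0,1,2) -> 0 ; (2,5,4): ranks (0,2,1) -> 1
        sym = ordinal_symbolize(np.array([3.0, 1.0, 2.0, 5.0, 4.0]), d=3, tau=1)
        assert sym.tolist() == [4, 0, 1]

    @pytest.mark.parametrize("d,tau", [(3, 1), (3, 4), (4, 2), (5, 1)])
    def test_output_length(self, rng, d, tau):
        x = rng.standard_normal(200)
        assert len(ordinal_symbolize(x, d, tau)) == 200 - (d - 1) * tau

    def test_ties_rank_earlier_smaller(self):
        sym = ordinal_symbolize(np.array([1.0, 1.0, 0.0]), d=3, tau=1)
        # ranks: first 1.0 -> 1, second 1.0 -> 2, 0.0 -> 0  => pattern (1,2,0)
        perms = sorted(itertools.permutations(range(3)))
        assert perms[sym[0]] == (1, 2, 0)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            sym = ordinal_symbolize(np.zeros(50), d=3, tau=1)
        assert len(set(sym.tolist())) == 1


class TestSymbolicTE:
    def test_matches_bruteforce_on_short_sequences(self, rng):
        for _ in range(5):
            x = rng.integers(0, 6, 60)
            y = rng.integers(0, 6, 60)
            te = symbolic_te(x, y, delta=2, alphabet=6)
            assert te == pytest.approx(
                max(brute_force_te(x.tolist(), y.tolist(), 2, 6), 0.0), abs=1e-12
            )

    def test_self_shifted_two_routes_agree(self, rng):
        x = rng.integers(0, 6, 50)
        te = symbolic_te(x, np.roll(x, 1), delta=1, alphabet=6)
        assert te == pytest.approx(
            max(brute_force_te(x.tolist(), np.roll(x, 1).tolist(), 1, 6), 0.0),
            abs=1e-12,
        )

    def test_deterministic_copy_reaches_log2_alphabet(self, rng):
        # y_{t+delta} = x_t with x iid uniform over 6 symbols: the source
        # fully determines the target future -> TE = log2 6 bits
        n = 10_000
        x = rng.integers(0, 6, n)
        delta = 1
        y = np.empty(n, dtype=int)
        y[delta:] = x[:-delta]
        y[:delta] = rng.integers(0, 6, delta)
        te = symbolic_te(x, y, delta=delta, alphabet=6)
        assert te == pytest.approx(np.log2(6), abs=0.05)

    def test_independent_streams_near_zero(self, rng):
        tes = []
        for _ in range(20):
            x = rng.integers(0, 6, 10_000)
            y = rng.integers(0, 6, 10_000)
            tes.append(symbolic_te(x, y, delta=1, alphabet=6))
        assert max(tes) <= 0.05  # plug-in bias bound

    def test_undersampling_warns(self, rng):
        with pytest.warns(UserWarning, match="undersampled"):
            symbolic_te(rng.integers(0, 6, 50), rng.integers(0, 6, 50),
                        delta=1, alphabet=6)

    def test_conditional_entropy_uniform(self, rng):
        y = rng.integers(0, 6, 200_000)
        assert conditional_entropy(y, 1, 6) == pytest.approx(np.log2(6), abs=0.01)


class TestNSTE:
    def test_affine_rescaling_invariance(self):
        x, y = gen_directed_pair(FS, 12, "gamma1", 1 / 160, 1.0, seed=0)
        p = NSTEParams(seed=0)
        base = nste(x, y, FS, "gamma1", p)
        scaled = nste(3.7 * x + 11.0, 0.2 * y - 5.0, FS, "gamma1", p)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_swapping_arguments_swaps_directions(self):
        x, y = gen_directed_pair(FS, 12, "gamma1", 1 / 160, 1.0, seed=1)
        p = NSTEParams(seed=3)
        assert nste(x, y, FS, "gamma1", p) == nste(x, y, FS, "gamma1", p)
        assert nste(y, x, FS, "gamma1", p) == nste(y, x, FS, "gamma1", p)

    def test_near_copy_strongly_directed(self, rng):
        x, _ = gen_directed_pair(FS, 20, "gamma1", 0.0, 0.0, seed=2)
        y = np.roll(x, 3) + 0.01 * rng.standard_normal(len(x))
        p = NSTEParams(seed=0, tau=3, delta=3)
        assert nste(x, y, FS, "gamma1", p) >= 0.8
        assert nste(y, x, FS, "gamma1", p) <= 0.1

    def test_lag_sign_flip_swaps_direction(self):
        p = NSTEParams(seed=0)
        x, y = gen_directed_pair(FS, 12, "gamma1", 1 / 160, 1.0, seed=5)
        xr, yr = gen_directed_pair(FS, 12, "gamma1", -1 / 160, 1.0, seed=5)
        assert nste(x, y, FS, "gamma1", p) > nste(y, x, FS, "gamma1", p)
        assert nste(yr, xr, FS, "gamma1", p) > nste(xr, yr, FS, "gamma1", p)

    def test_short_window_rejected(self, rng):
        x = rng.standard_normal(int(5 * FS))
        with pytest.raises(ValueError, match="10 s"):
            nste(x, x.copy(), FS, "gamma1")

    def test_constant_target_rejected(self, rng):
        x = rng.standard_normal(int(12 * FS))
        p = NSTEParams(seed=0, tau=3, delta=3)
        from gammasurge.nste import _nste_from_symbols

        with pytest.raises(ValueError, match="entropy"):
            _nste_from_symbols(
                ordinal_symbolize(x, 3, 3), np.zeros(100, dtype=int), 3, p,
                np.random.default_rng(0),
            )


def _directed_session(seed):
    base = {ch: {"gamma1": 1.0} for ch in ("T5", "P3", "O1", "F4", "F7", "F8")}
    quarter = 1.0 / (4 * BANDS["gamma1"].center)
    stage = StageSpec(
        label="S1", duration=35.0, band_amp=base,
        dir_links=[DirLink("T5", "P3", "gamma1", quarter, 4.0)],
    )
    return gen_session(SessionSpec(stages=[stage], seed=seed))


class TestDirectedBandMatrix:
    CHANS = ["T5", "P3", "O1", "F4"]

    def test_injected_link_is_argmax_and_asymmetric(self):
        rec, _, _ = _directed_session(1)
        mat = directed_band_matrix(rec, "gamma1", NSTEParams(seed=0),
                                   channels=self.CHANS)
        v = mat.values.to_numpy()
        i, j = np.unravel_index(np.nanargmax(v), v.shape)
        assert (self.CHANS[i], self.CHANS[j]) == ("T5", "P3")
        assert v[i, j] >= 3 * mat.values.loc["P3", "T5"]

    def test_channel_permutation_equivariance(self):
        rec, _, _ = _directed_session(2)
        perm = ["P3", "F4", "T5", "O1"]
        a = directed_band_matrix(rec, "gamma1", NSTEParams(seed=0),
                                 channels=self.CHANS)
        b = directed_band_matrix(rec, "gamma1", NSTEParams(seed=0),
                                 channels=perm)
        assert np.allclose(
            a.values.loc[perm, perm].to_numpy(), b.values.to_numpy(),
            equal_nan=True,
        )

    def test_values_bounded(self):
        rec, _, _ = _directed_session(3)
        mat = directed_band_matrix(rec, "gamma1", NSTEParams(seed=0),
                                   channels=self.CHANS)
        v = mat.values.to_numpy()
        assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1
        assert np.isnan(np.diag(v)).all()


class TestFFFBSummary:
    def _matrix(self, values, chans):
        return NSTEMatrix(
            values=pd.DataFrame(values, index=chans, columns=chans),
            band=BANDS["gamma1"],
        )

    def test_symmetric_matrix_ff_equals_fb(self, rng):
        chans = ["T5", "P3", "O1", "Fp1", "F7", "F3", "Fp2", "F4", "F8"]
        v = rng.uniform(0, 1, (9, 9))
        v = (v + v.T) / 2
        ff, fb, _ = ff_fb_summary(self._matrix(v, chans), "left")
        assert ff == pytest.approx(fb)

    def test_hand_computed_means(self):
        chans = ["T5", "P3", "O1", "Fp1", "F7", "F3", "Fp2", "F4", "F8"]
        v = np.zeros((9, 9))
        v[0, 4] = 0.6  # T5 -> F7
        v[4, 0] = 0.2  # F7 -> T5
        ff, fb, table = ff_fb_summary(self._matrix(v, chans), "left")
        assert ff == pytest.approx(0.6 / 18)
        assert fb == pytest.approx(0.2 / 18)
        assert len(table) == 18
        tags = dict(zip(zip(table.posterior, table.frontal), table.tag))
        assert tags[("T5", "F8")] == "contra" and tags[("T5", "F7")] == "ipsi"

    def test_missing_channel_rejected(self):
        chans = ["T5", "P3", "O1"]
        with pytest.raises(KeyError):
            ff_fb_summary(self._matrix(np.zeros((3, 3)), chans), "left")
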