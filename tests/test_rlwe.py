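"""Unit and property tests for the somewhat-homomorphic layer."""

import numpy as np
import pytest

from pirvcf import rlwe
from pirvcf.ntt import negacyclic_schoolbook, ring_context
from pirvcf.rlwe import (
    NoiseBudgetWarning,
    Plaintext,
    PlaintextNtt,
    RlweParams,
    absorb,
    add,
    ct_from_bytes,
    ct_to_bytes,
    decrypt,
    encrypt,
    keygen,
    keypair_from_bytes,
    keypair_to_bytes,
    scalar_mask,
    sub_plain,
)


def random_plain(params, rng):
    return Plaintext(rng.integers(0, params.t, params.degree), params)


class TestParams:
    def test_profile_string_round_trip(self):
        p = RlweParams.from_string("FV:80:1024:62:14")
        assert (p.security_bits, p.degree, p.coeff_bits, p.absorb_bits) == (
            80, 1024, 62, 14,
        )
        assert p.to_string() == "FV:80:1024:62:14"

    @pytest.mark.parametrize("profile", ["FV:80:1024:62:14", "FV:16:64:40:8", "FV:8:16:20:4"])
    def test_modulus_invariants(self, profile):
        p = RlweParams.from_string(profile)
        assert (1 << (p.coeff_bits - 1)) < p.q <= (1 << p.coeff_bits)
        assert p.t == 1 << p.absorb_bits
        assert p.t < p.q

    def test_degree_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            keygen(RlweParams(8, 24, 20, 4))


class TestRoundTrip:
    def test_zero_round_trip_default(self, default_fv):
        kp = keygen(default_fv, seed=1)
        ct = encrypt(kp, 0, np.random.default_rng(2))
        assert (decrypt(kp, ct).coeffs == 0).all()

    def test_keygen_probabilistic(self, default_fv):
        k1, k2 = keygen(default_fv, seed=1), keygen(default_fv, seed=2)
        assert not (k1.public[1] == k2.public[1]).all()
        assert k1.key_id != k2.key_id

    def test_keygen_deterministic_given_seed(self, tiny_fv):
        assert keygen(tiny_fv, seed=9).key_id == keygen(tiny_fv, seed=9).key_id

    def test_toy_ring_random_sweep(self, tiny_fv):
        kp = keygen(tiny_fv, seed=3)
        rng = np.random.default_rng(4)
        for _ in range(100):
            m = random_plain(tiny_fv, rng)
            assert decrypt(kp, encrypt(kp, m, rng)) == m

    def test_one_hot_round_trip(self, default_fv):
        kp = keygen(default_fv, seed=5)
        m = Plaintext.constant(1, default_fv)
        assert decrypt(kp, encrypt(kp, m, np.random.default_rng(6))) == m

    def test_coefficient_out_of_range_rejected(self, tiny_fv):
        with pytest.raises(ValueError):
            Plaintext(np.full(tiny_fv.degree, tiny_fv.t), tiny_fv)


class TestProbabilisticEncryption:
    def test_two_encryptions_differ(self, tiny_fv):
        kp = keygen(tiny_fv, seed=7)
        rng = np.random.default_rng(8)
        c1, c2 = encrypt(kp, 0, rng), encrypt(kp, 0, rng)
        assert not (c1.c0 == c2.c0).all()
        assert (decrypt(kp, c1).coeffs == 0).all() and (decrypt(kp, c2).coeffs == 0).all()

    def test_thousand_distinct_serializations(self, tiny_fv):
        kp = keygen(tiny_fv, seed=9)
        rng = np.random.default_rng(10)
        blobs = {ct_to_bytes(encrypt(kp, 1, rng)) for _ in range(1000)}
        assert len(blobs) == 1000

    def test_zero_one_ciphertexts_indistinguishable(self, tiny_fv):
        """Byte histograms of enc(0) vs enc(1) pass a chi-square two-sample test."""
        from scipy.stats import chi2_contingency

        kp = keygen(tiny_fv, seed=11)
        rng = np.random.default_rng(12)
        skip = 6 + len(tiny_fv.to_string()) + 8 + 8  # header is constant, drop it
        hists = []
        for m in (0, 1):
            data = b"".join(ct_to_bytes(encrypt(kp, m, rng))[skip:] for _ in range(1000))
            hists.append(np.bincount(np.frombuffer(data, dtype=np.uint8), minlength=256))
        counts = np.array(hists)
        counts = counts[:, counts.sum(axis=0) > 0]
        _, pvalue, _, _ = chi2_contingency(counts)
        assert pvalue > 0.01


class TestHomomorphisms:
    def test_absorb_one_and_zero(self, default_fv):
        kp = keygen(default_fv, seed=13)
        rng = np.random.default_rng(14)
        y = random_plain(default_fv, rng)
        assert decrypt(kp, absorb(encrypt(kp, 1, rng), y)) == y
        erased = decrypt(kp, absorb(encrypt(kp, 0, rng), y))
        assert (erased.coeffs == 0).all()

    def test_absorb_matches_schoolbook_oracle(self, tiny_fv):
        kp = keygen(tiny_fv, seed=15)
        rng = np.random.default_rng(16)
        for _ in range(50):
            m, p = random_plain(tiny_fv, rng), random_plain(tiny_fv, rng)
            got = decrypt(kp, absorb(encrypt(kp, m, rng), p)).coeffs
            ref = negacyclic_schoolbook(m.coeffs, p.coeffs, tiny_fv.degree, tiny_fv.t)
            assert [int(x) for x in got] == ref

    def test_add_random_sweep(self, tiny_fv):
        kp = keygen(tiny_fv, seed=17)
        rng = np.random.default_rng(18)
        for _ in range(50):
            a, b = random_plain(tiny_fv, rng), random_plain(tiny_fv, rng)
            got = decrypt(kp, add(encrypt(kp, a, rng), encrypt(kp, b, rng))).coeffs
            assert ((a.coeffs + b.coeffs) % tiny_fv.t == got).all()

    def test_add_zero_is_identity(self, tiny_fv):
        kp = keygen(tiny_fv, seed=19)
        rng = np.random.default_rng(20)
        m = random_plain(tiny_fv, rng)
        assert decrypt(kp, add(encrypt(kp, m, rng), encrypt(kp, 0, rng))) == m

    def test_sub_plain_self_is_zero(self, tiny_fv):
        kp = keygen(tiny_fv, seed=21)
        rng = np.random.default_rng(22)
        h = random_plain(tiny_fv, rng)
        assert (decrypt(kp, sub_plain(encrypt(kp, h, rng), h)).coeffs == 0).all()

    def test_parameter_mismatch_rejected(self, tiny_fv, default_fv):
        k1, k2 = keygen(tiny_fv, seed=23), keygen(tiny_fv, seed=24)
        rng = np.random.default_rng(25)
        with pytest.raises(ValueError):
            add(encrypt(k1, 0, rng), encrypt(k2, 0, rng))


class TestScalarMask:
    def test_units_fix_exactly_zero(self):
        """In Z_16, u·c = 0 mod 16 iff c = 0, for every odd u (exhaustive)."""
        t = 16
        for u in range(1, t, 2):
            for c in range(t):
                assert ((u * c) % t == 0) == (c == 0)

    def test_mask_preserves_zero_pattern(self, tiny_fv):
        kp = keygen(tiny_fv, seed=26)
        rng = np.random.default_rng(27)
        coeffs = rng.integers(0, tiny_fv.t, tiny_fv.degree)
        coeffs[::3] = 0
        m = Plaintext(coeffs, tiny_fv)
        got = decrypt(kp, scalar_mask(encrypt(kp, m, rng), 7)).coeffs
        assert ((got == 0) == (coeffs == 0)).all()
        assert (got == coeffs * 7 % tiny_fv.t).all()

    def test_mask_zero_polynomial_stays_zero(self, tiny_fv):
        kp = keygen(tiny_fv, seed=28)
        ct = scalar_mask(encrypt(kp, 0, np.random.default_rng(29)), 15)
        assert (decrypt(kp, ct).coeffs == 0).all()

    def test_unit_one_is_identity(self, tiny_fv):
        kp = keygen(tiny_fv, seed=30)
        rng = np.random.default_rng(31)
        h = random_plain(tiny_fv, rng)
        assert decrypt(kp, scalar_mask(encrypt(kp, h, rng), 1)) == h

    @pytest.mark.parametrize("u", [0, 2, 8, 16])
    def test_non_units_rejected(self, tiny_fv, u):
        kp = keygen(tiny_fv, seed=32)
        with pytest.raises(ValueError):
            scalar_mask(encrypt(kp, 0, np.random.default_rng(33)), u)


class TestNoiseBudget:
    def test_absorb_strictly_decreases_budget(self, default_fv):
        kp = keygen(default_fv, seed=34)
        rng = np.random.default_rng(35)
        ct = encrypt(kp, 1, rng)
        after = absorb(ct, Plaintext.constant(1, default_fv))
        assert after.noise_budget < ct.noise_budget

    def test_adds_never_increase_budget(self, tiny_fv):
        kp = keygen(tiny_fv, seed=36)
        rng = np.random.default_rng(37)
        ct = encrypt(kp, 0, rng)
        other = encrypt(kp, 0, rng)
        budgets = [ct.noise_budget]
        for _ in range(10):
            ct = add(ct, other)
            budgets.append(ct.noise_budget)
        assert all(b2 < b1 for b1, b2 in zip(budgets, budgets[1:]))

    def test_absorb_plus_row_of_adds_still_exact(self, default_fv):
        """One absorption followed by row_size−1 additions decrypts exactly."""
        kp = keygen(default_fv, seed=38)
        rng = np.random.default_rng(39)
        y = PlaintextNtt(Plaintext(rng.integers(0, default_fv.t, default_fv.degree), default_fv))
        acc = absorb(encrypt(kp, 1, rng), y)
        noise_term = absorb(encrypt(kp, 0, rng), PlaintextNtt(
            Plaintext(rng.integers(0, default_fv.t, default_fv.degree), default_fv)))
        for _ in range(715):
            acc = add(acc, noise_term)
        assert acc.noise_budget > 0
        assert (decrypt(kp, acc).coeffs == y.coeffs).all()

    def test_over_absorbed_ciphertext_flagged(self, tiny_fv):
        kp = keygen(tiny_fv, seed=40)
        rng = np.random.default_rng(41)
        ct = encrypt(kp, 1, rng)
        p = PlaintextNtt(random_plain(tiny_fv, rng))
        while ct.noise_budget > 0:
            ct = absorb(ct, p)
        with pytest.warns(NoiseBudgetWarning):
            decrypt(kp, ct)

    def test_budget_predicts_correct_chains(self, tiny_fv):
        """Monte-Carlo: random op chains whose budget stays positive decrypt exactly."""
        kp = keygen(tiny_fv, seed=42)
        rng = np.random.default_rng(43)
        for _ in range(200):
            m = random_plain(tiny_fv, rng)
            ct = encrypt(kp, m, rng)
            expect = m.coeffs.copy()
            for _ in range(rng.integers(1, 6)):
                op = rng.integers(0, 3)
                if op == 0:
                    p = random_plain(tiny_fv, rng)
                    cand = absorb(ct, p)
                    if cand.noise_budget <= 0:
                        continue
                    from pirvcf.ntt import negacyclic_schoolbook

                    expect = np.array(
                        negacyclic_schoolbook(expect, p.coeffs, tiny_fv.degree, tiny_fv.t)
                    )
                    ct = cand
                elif op == 1:
                    other = random_plain(tiny_fv, rng)
                    ct = add(ct, encrypt(kp, other, rng))
                    expect = (expect + other.coeffs) % tiny_fv.t
                else:
                    u = int(rng.integers(0, tiny_fv.t // 2)) * 2 + 1
                    cand = scalar_mask(ct, u)
                    if cand.noise_budget <= 0:
                        continue
                    ct = cand
                    expect = expect * u % tiny_fv.t
            if ct.noise_budget > 0:
                assert (decrypt(kp, ct).coeffs == expect).all()


class TestSerialization:
    def test_ciphertext_round_trip(self, tiny_fv):
        kp = keygen(tiny_fv, seed=44)
        rng = np.random.default_rng(45)
        m = random_plain(tiny_fv, rng)
        ct = encrypt(kp, m, rng)
        ct2 = ct_from_bytes(ct_to_bytes(ct))
        assert decrypt(kp, ct2) == m
        assert ct2.log2_noise == ct.log2_noise

    def test_serialized_size_is_constant(self, tiny_fv):
        kp = keygen(tiny_fv, seed=46)
        rng = np.random.default_rng(47)
        sizes = {len(ct_to_bytes(encrypt(kp, int(i) % 2, rng))) for i in range(8)}
        assert sizes == {rlwe.serialized_size(tiny_fv)}

    def test_keypair_round_trip(self, tiny_fv):
        kp = keygen(tiny_fv, seed=48)
        kp2 = keypair_from_bytes(keypair_to_bytes(kp))
        rng = np.random.default_rng(49)
        m = random_plain(tiny_fv, rng)
        assert decrypt(kp2, encrypt(kp2, m, rng)) == m
        assert kp2.key_id == kp.key_id
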