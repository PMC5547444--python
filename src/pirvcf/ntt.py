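"""Negacyclic number-theoretic transforms over word-sized prime moduli.

The somewhat-homomorphic layer works in R_q = Z_q[x]/(x^n + 1).  To keep every
modular product below 64 bits (and therefore vectorizable with numpy's uint64
arithmetic), q is either a single NTT-friendly prime of exactly ``coeff_bits``
bits, or — for moduli wider than 31 bits — a product of two NTT-friendly
primes whose product has exactly ``coeff_bits`` bits.  Each prime carries its
own transform plan; residues travel in an (n_limbs, degree) array and are
recombined with the CRT only when a canonical integer representation mod q is
needed (decryption, serialization).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import sympy


def is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def find_ntt_prime(bits: int, degree: int, minimum: int | None = None) -> int:
    """Smallest prime p with exactly `bits` bits, p ≡ 1 (mod 2·degree), p ≥ minimum."""
    step = 2 * degree
    lo = 1 << (bits - 1)
    hi = 1 << bits
    start = max(lo, minimum or 0)
    # first candidate ≥ start congruent to 1 mod step
    p = start + (1 - start) % step
    if p < start:
        p += step
    while p < hi:
        if sympy.isprime(p):
            return p
        p += step
    raise ValueError(f"no {bits}-bit prime ≡ 1 mod {step}")


@lru_cache(maxsize=None)
def _plan(p: int, degree: int) -> "NttPlan":
    return NttPlan(p, degree)


class NttPlan:
    """Radix-2 negacyclic NTT for one prime, fully vectorized per stage."""

    def __init__(self, p: int, degree: int):
        if not is_power_of_two(degree):
            raise ValueError("degree must be a power of two")
        if (p - 1) % (2 * degree) != 0:
            raise ValueError("prime not NTT-friendly for this degree")
        self.p = p
        self.n = degree
        g = sympy.primitive_root(p)
        psi = pow(g, (p - 1) // (2 * degree), p)  # primitive 2n-th root
        omega = psi * psi % p
        n_inv = pow(degree, p - 2, p)

        logn = degree.bit_length() - 1
        rev = np.zeros(degree, dtype=np.int64)
        for i in range(degree):
            rev[i] = int(format(i, f"0{logn}b")[::-1], 2) if logn else 0
        self._rev = rev

        # stage twiddles: stage s has half-block size m = 2^s, twiddles w_{2m}^j
        self._fwd_tw = []
        self._inv_tw = []
        iomega = pow(omega, p - 2, p)
        for s in range(logn):
            m = 1 << s
            w = pow(omega, degree // (2 * m), p)
            iw = pow(iomega, degree // (2 * m), p)
            self._fwd_tw.append(
                np.array([pow(w, j, p) for j in range(m)], dtype=np.uint64)
            )
            self._inv_tw.append(
                np.array([pow(iw, j, p) for j in range(m)], dtype=np.uint64)
            )
        ipsi = pow(psi, p - 2, p)
        self._psi_pow = np.array(
            [pow(psi, i, p) for i in range(degree)], dtype=np.uint64
        )
        # fold 1/n into the inverse psi powers
        self._ipsi_pow = np.array(
            [pow(ipsi, i, p) * n_inv % p for i in range(degree)], dtype=np.uint64
        )

    def _core(self, a: np.ndarray, tables: list[np.ndarray]) -> np.ndarray:
        p = np.uint64(self.p)
        a = a[self._rev]
        for w in tables:
            m = w.shape[0]
            a = a.reshape(-1, 2, m)
            lo = a[:, 0, :]
            hi = a[:, 1, :] * w % p
            a = np.stack(((lo + hi) % p, (lo + (p - hi)) % p), axis=1)
        return a.reshape(-1)

    def forward(self, coeffs: np.ndarray) -> np.ndarray:
        """Coefficient → evaluation domain (negacyclic)."""
        a = coeffs.astype(np.uint64) * self._psi_pow % np.uint64(self.p)
        return self._core(a, self._fwd_tw)

    def inverse(self, evals: np.ndarray) -> np.ndarray:
        a = self._core(evals.astype(np.uint64), self._inv_tw)
        return a * self._ipsi_pow % np.uint64(self.p)


@lru_cache(maxsize=None)
def ring_context(degree: int, coeff_bits: int) -> "RingContext":
    return RingContext(degree, coeff_bits)


class RingContext:
    """Arithmetic in R_q for a (degree, coeff_bits) pair, in RNS/eval form."""

    def __init__(self, degree: int, coeff_bits: int):
        if not is_power_of_two(degree):
            raise ValueError("degree must be a power of two")
        if coeff_bits < 8:
            raise ValueError("coeff_bits too small")
        self.n = degree
        self.coeff_bits = coeff_bits
        if coeff_bits <= 31:
            self.primes = (find_ntt_prime(coeff_bits, degree),)
        else:
            half = (coeff_bits + 1) // 2
            # p1 slightly above 2^((C-1)/2) so the product lands in [2^(C-1), 2^C)
            p1 = find_ntt_prime(half, degree, minimum=math.isqrt(1 << (coeff_bits - 1)) + 1)
            lo = (1 << (coeff_bits - 1)) // p1 + 1
            p2 = find_ntt_prime(half, degree, minimum=max(lo, p1 + 2 * degree))
            self.primes = (p1, p2)
        self.q = 1
        for p in self.primes:
            if p >= 1 << 31:
                raise ValueError("limb prime exceeds 31 bits")
            self.q *= p
        if not (1 << (coeff_bits - 1)) < self.q <= (1 << coeff_bits):
            raise AssertionError("modulus misses the requested bit length")
        self.plans = tuple(_plan(p, degree) for p in self.primes)
        self._parr = np.array(self.primes, dtype=np.uint64)[:, None]
        if len(self.primes) == 2:
            p1, p2 = self.primes
            self._inv_p1_mod_p2 = np.uint64(pow(p1, p2 - 2, p2))

    # ---- residue layout helpers -------------------------------------------------
    def residues_from_signed(self, coeffs: np.ndarray) -> np.ndarray:
        """int64 coefficients (any sign, |c| < 2^31) → (L, n) residue array."""
        c = coeffs.astype(np.int64)[None, :]
        return (c % self._parr.astype(np.int64)).astype(np.uint64)

    def to_ntt(self, coeffs: np.ndarray) -> np.ndarray:
        res = self.residues_from_signed(coeffs)
        return np.stack([pl.forward(res[i]) for i, pl in enumerate(self.plans)])

    def from_ntt(self, evals: np.ndarray) -> np.ndarray:
        """(L, n) eval-domain element → uint64 array of canonical residues mod q."""
        res = np.stack([pl.inverse(evals[i]) for i, pl in enumerate(self.plans)])
        return self.crt(res)

    def crt(self, res: np.ndarray) -> np.ndarray:
        if len(self.primes) == 1:
            return res[0]
        p1, p2 = (np.uint64(p) for p in self.primes)
        x1, x2 = res[0], res[1]
        d = (x2 + (p2 - x1 % p2)) % p2
        return x1 + np.uint64(self.primes[0]) * (d * self._inv_p1_mod_p2 % p2)

    # ---- eval-domain arithmetic ---------------------------------------------------
    def add(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a + b) % self._parr

    def sub(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a + (self._parr - b)) % self._parr

    def mul(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return a * b % self._parr

    def scalar(self, value: int) -> np.ndarray:
        """Broadcastable (L, 1) residue representation of an integer mod q."""
        return np.array([value % p for p in self.primes], dtype=np.uint64)[:, None]

    def neg(self, a: np.ndarray) -> np.ndarray:
        return (self._parr - a) % self._parr

    def zero(self) -> np.ndarray:
        return np.zeros((len(self.primes), self.n), dtype=np.uint64)

    # ---- sampling ------------------------------------------------------------------
    def sample_uniform(self, rng: np.random.Generator) -> np.ndarray:
        return np.stack(
            [rng.integers(0, p, self.n, dtype=np.uint64) for p in self.primes]
        )


def negacyclic_schoolbook(a, b, n: int, modulus: int):
    """O(n^2) reference product in Z_modulus[x]/(x^n + 1), exact big-int arithmetic.

    Independent of the NTT path on purpose: plain Python integers, no numpy
    modular tricks.  Used as the oracle for absorb/add on small rings.
    """
    out = [0] * n
    for i in range(n):
        ai = int(a[i])
        if ai == 0:
            continue
        for j in range(n):
            k = i + j
            term = ai * int(b[j])
            if k >= n:
                out[k - n] = (out[k - n] - term) % modulus
            else:
                out[k] = (out[k] + term) % modulus
    return [v % modulus for v in out]
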