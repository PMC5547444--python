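"""Somewhat-homomorphic encryption over polynomial rings (FV-style).

The scheme implements exactly what the private-retrieval protocol needs:
encryption of small plaintext polynomials, ciphertext addition, *absorption*
(ciphertext × plaintext, so HE(1)·y = HE(y) and HE(0)·y = HE(0)), plaintext
subtraction, and multiplication by a unit scalar used for masking.  There is
no relinearization and no ciphertext-ciphertext multiplication — the protocol
never multiplies two ciphertexts.

Plaintexts live in R_t = Z_t[x]/(x^n+1) with t = 2^absorb_bits; ciphertexts
are pairs of R_q elements kept in NTT (evaluation) form so that every
homomorphic operation is a pointwise vector operation.

Noise is tracked as a running upper bound on the standard deviation of the
decryption error term (log2 domain), with a 6-sigma tailcut when converting
the bound to a correctness budget in bits.  The bound is an estimate, never a
measurement of the secret noise; `decrypt` emits a warning when the budget is
exhausted and correctness is no longer guaranteed.
"""

from __future__ import annotations

import hashlib
import math
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ntt import RingContext, is_power_of_two, ring_context

_CT_MAGIC = b"PVCT"
_CT_VERSION = 1

#: log2 of the tail factor applied to the noise std bound
_TAIL_BITS = math.log2(6.0)
#: extra slack (bits) covering the Δ = floor(q/t) rounding residue
_DELTA_SLACK_BITS = 1.0


class NoiseBudgetWarning(UserWarning):
    """Raised-as-warning when a ciphertext is decrypted past its noise budget."""


@dataclass(frozen=True)
class RlweParams:
    """FV parameter profile, written ``FV:A:B:C:D`` in configuration files.

    A = advertised security bits, B = ring degree (power of two), C = bit
    length of the ciphertext modulus q, D = plaintext bits absorbed per
    coefficient (t = 2^D).
    """

    security_bits: int
    degree: int
    coeff_bits: int
    absorb_bits: int
    noise_std: float = 3.2

    def __post_init__(self):
        if not is_power_of_two(self.degree):
            raise ValueError("degree must be a power of two")
        if self.absorb_bits < 1 or self.absorb_bits >= self.coeff_bits:
            raise ValueError("absorb_bits must satisfy 0 < D < C")
        if self.noise_std <= 0:
            raise ValueError("noise_std must be positive")

    @property
    def t(self) -> int:
        return 1 << self.absorb_bits

    @property
    def ring(self) -> RingContext:
        return ring_context(self.degree, self.coeff_bits)

    @property
    def q(self) -> int:
        return self.ring.q

    @classmethod
    def from_string(cls, profile: str) -> "RlweParams":
        parts = profile.split(":")
        if parts and parts[0].upper() == "FV":
            parts = parts[1:]
        if len(parts) != 4:
            raise ValueError(f"cannot parse FV profile {profile!r}")
        a, b, c, d = (int(p) for p in parts)
        return cls(a, b, c, d)

    def to_string(self) -> str:
        return f"FV:{self.security_bits}:{self.degree}:{self.coeff_bits}:{self.absorb_bits}"

    # ---- noise model ------------------------------------------------------------
    def fresh_noise_log2(self) -> float:
        """log2 std bound of the decryption-error term of a fresh encryption.

        e·u + e1 + e2·s with ternary u, s (variance 2/3) and Gaussian errors.
        """
        var = 2 * self.degree * self.noise_std**2 * (2 / 3) + self.noise_std**2
        return 0.5 * math.log2(var)

    def budget_from_noise(self, log2_noise: float) -> float:
        delta = self.q // self.t
        return math.log2(delta / 2) - _DELTA_SLACK_BITS - _TAIL_BITS - log2_noise


@dataclass
class Plaintext:
    """Element of R_t: `degree` coefficients in [0, t)."""

    coeffs: np.ndarray
    params: RlweParams

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.int64)
        if self.coeffs.shape != (self.params.degree,):
            raise ValueError("plaintext length must equal the ring degree")
        if (self.coeffs < 0).any() or (self.coeffs >= self.params.t).any():
            raise ValueError("plaintext coefficients out of [0, t)")

    @classmethod
    def constant(cls, value: int, params: RlweParams) -> "Plaintext":
        c = np.zeros(params.degree, dtype=np.int64)
        c[0] = value
        return cls(c, params)

    @classmethod
    def zero(cls, params: RlweParams) -> "Plaintext":
        return cls(np.zeros(params.degree, dtype=np.int64), params)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Plaintext)
            and self.params == other.params
            and bool((self.coeffs == other.coeffs).all())
        )


class PlaintextNtt:
    """Plaintext pre-lifted to the evaluation domain, cached for absorption."""

    __slots__ = ("evals", "params", "l2", "coeffs")

    def __init__(self, pt: Plaintext):
        self.params = pt.params
        self.coeffs = pt.coeffs
        self.evals = pt.params.ring.to_ntt(pt.coeffs)
        self.l2 = float(np.linalg.norm(pt.coeffs.astype(np.float64)))


@dataclass
class Ciphertext:
    """Pair of R_q elements (NTT domain) plus a running noise estimate."""

    c0: np.ndarray
    c1: np.ndarray
    params: RlweParams
    log2_noise: float
    key_id: bytes = b""

    @property
    def noise_budget(self) -> float:
        """Bits of correctness margin remaining (conservative estimate)."""
        return self.params.budget_from_noise(self.log2_noise)


@dataclass(frozen=True)
class HeKeyPair:
    params: RlweParams
    public: tuple[np.ndarray, np.ndarray]  # (b, a), NTT domain
    secret: np.ndarray  # s, NTT domain
    key_id: bytes = b""


def _check_compatible(a: Ciphertext, b: Ciphertext) -> None:
    if a.params != b.params or (a.key_id and b.key_id and a.key_id != b.key_id):
        raise ValueError("ciphertexts use different parameters or keys")


def _gauss(params: RlweParams, rng: np.random.Generator) -> np.ndarray:
    tail = 6.0 * params.noise_std
    e = np.rint(rng.normal(0.0, params.noise_std, params.degree))
    return np.clip(e, -tail, tail).astype(np.int64)


def _ternary(params: RlweParams, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(-1, 2, params.degree, dtype=np.int64)


def keygen(params: RlweParams, seed=None) -> HeKeyPair:
    """Generate an RLWE keypair; deterministic when `seed` is given."""
    rng = np.random.default_rng(seed)
    ring = params.ring
    s = ring.to_ntt(_ternary(params, rng))
    e = ring.to_ntt(_gauss(params, rng))
    a = ring.sample_uniform(rng)
    b = ring.sub(ring.zero(), ring.add(ring.mul(a, s), e))  # b = -(a·s + e)
    key_id = hashlib.blake2b(
        b.tobytes() + a.tobytes() + params.to_string().encode(), digest_size=8
    ).digest()
    return HeKeyPair(params=params, public=(b, a), secret=s, key_id=key_id)


def encrypt(pk: HeKeyPair, m: Plaintext | int, rng=None) -> Ciphertext:
    """Probabilistic encryption of m (an R_t element or a constant)."""
    params = pk.params
    if isinstance(m, (int, np.integer)):
        m = Plaintext.constant(int(m), params)
    if m.params != params:
        raise ValueError("plaintext parameters do not match the key")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ring = params.ring
    b, a = pk.public
    u = ring.to_ntt(_ternary(params, rng))
    e1 = ring.to_ntt(_gauss(params, rng))
    e2 = ring.to_ntt(_gauss(params, rng))
    delta = ring.scalar(params.q // params.t)
    m_ntt = ring.to_ntt(m.coeffs)
    c0 = ring.add(ring.add(ring.mul(b, u), e1), ring.mul(delta, m_ntt))
    c1 = ring.add(ring.mul(a, u), e2)
    return Ciphertext(c0, c1, params, params.fresh_noise_log2(), pk.key_id)


def decrypt(sk: HeKeyPair, ct: Ciphertext) -> Plaintext:
    """Recover the plaintext; warns when the noise budget is exhausted."""
    params = ct.params
    if sk.params != params or (ct.key_id and ct.key_id != sk.key_id):
        raise ValueError("ciphertext does not match this key")
    if ct.noise_budget <= 0:
        warnings.warn(
            "noise budget exhausted: decryption is no longer guaranteed correct",
            NoiseBudgetWarning,
            stacklevel=2,
        )
    ring = params.ring
    x = ring.from_ntt(ring.add(ct.c0, ring.mul(ct.c1, sk.secret)))
    # m = round(t·x/q) mod t, exact big-int arithmetic
    xo = x.astype(object)
    t, q = params.t, params.q
    m = (xo * t + q // 2) // q % t
    return Plaintext(m.astype(np.int64), params)


def absorb(ct: Ciphertext, p: Plaintext | PlaintextNtt) -> Ciphertext:
    """Ciphertext × plaintext, the PIR work-horse: HE(1)·y = HE(y)."""
    if isinstance(p, Plaintext):
        p = PlaintextNtt(p)
    if p.params != ct.params:
        raise ValueError("parameter mismatch in absorb")
    ring = ct.params.ring
    # noise std bound grows by the plaintext l2 norm; floor sqrt(2) keeps the
    # budget strictly decreasing even for monomial plaintexts
    factor = max(math.sqrt(2.0), p.l2)
    return Ciphertext(
        ring.mul(ct.c0, p.evals),
        ring.mul(ct.c1, p.evals),
        ct.params,
        ct.log2_noise + math.log2(factor),
        ct.key_id,
    )


def add(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    _check_compatible(ct1, ct2)
    ring = ct1.params.ring
    noise = 0.5 * math.log2(2 ** (2 * ct1.log2_noise) + 2 ** (2 * ct2.log2_noise))
    return Ciphertext(
        ring.add(ct1.c0, ct2.c0),
        ring.add(ct1.c1, ct2.c1),
        ct1.params,
        noise,
        ct1.key_id or ct2.key_id,
    )


def sub_plain(ct: Ciphertext, p: Plaintext | PlaintextNtt) -> Ciphertext:
    """Subtract a plaintext: decrypt(sub_plain(enc(m), p)) = m - p mod t."""
    if isinstance(p, Plaintext):
        p = PlaintextNtt(p)
    if p.params != ct.params:
        raise ValueError("parameter mismatch in sub_plain")
    ring = ct.params.ring
    delta = ring.scalar(ct.params.q // ct.params.t)
    return Ciphertext(
        ring.sub(ct.c0, ring.mul(delta, p.evals)),
        ct.c1,
        ct.params,
        ct.log2_noise,
        ct.key_id,
    )


def scalar_mask(ct: Ciphertext, u: int) -> Ciphertext:
    """Multiply the underlying plaintext by a unit scalar u (odd, since t=2^D).

    Zero coefficients stay zero, nonzero stay nonzero — the one-time
    multiplicative pad of the subtraction step.
    """
    t = ct.params.t
    u = int(u)
    if not (0 < u < t) or u % 2 == 0:
        raise ValueError("mask must be an odd unit in [1, t)")
    ring = ct.params.ring
    s = ring.scalar(u)
    return Ciphertext(
        ring.mul(ct.c0, s),
        ring.mul(ct.c1, s),
        ct.params,
        ct.log2_noise + math.log2(max(1, u)),
        ct.key_id,
    )


def noise_budget(ct: Ciphertext) -> float:
    """Remaining correctness margin in bits (estimate, non-increasing)."""
    return ct.noise_budget


# ---- serialization ------------------------------------------------------------------


def _coeff_width(params: RlweParams) -> int:
    return (params.coeff_bits + 7) // 8


def serialized_size(params: RlweParams) -> int:
    """Byte length of one serialized ciphertext (fixed per parameter set)."""
    header = len(_CT_MAGIC) + 1 + 1 + len(params.to_string()) + 8 + 8
    return header + 2 * params.degree * _coeff_width(params)


def ring_elem_to_bytes(params: RlweParams, evals: np.ndarray) -> bytes:
    """Canonical bytes of an NTT-domain R_q element: n × ceil(C/8) LE words."""
    ring = params.ring
    width = _coeff_width(params)
    coeffs = ring.from_ntt(evals).astype(object)
    buf = np.zeros((params.degree, width), dtype=np.uint8)
    for b in range(width):
        buf[:, b] = (coeffs >> (8 * b) & 0xFF).astype(np.uint8)
    return buf.tobytes()


def ring_elem_from_bytes(params: RlweParams, data: bytes, offset: int = 0) -> np.ndarray:
    ring = params.ring
    width = _coeff_width(params)
    buf = np.frombuffer(
        data, dtype=np.uint8, count=params.degree * width, offset=offset
    ).reshape(params.degree, width)
    coeffs = np.zeros(params.degree, dtype=object)
    for b in range(width - 1, -1, -1):
        coeffs = (coeffs << 8) | buf[:, b].astype(object)
    res = np.stack([(coeffs % p).astype(np.uint64) for p in ring.primes])
    return np.stack([pl.forward(res[i]) for i, pl in enumerate(ring.plans)])


def ring_elem_size(params: RlweParams) -> int:
    return params.degree * _coeff_width(params)


def ct_to_bytes(ct: Ciphertext) -> bytes:
    """Canonical serialization: header + two little-endian coefficient arrays."""
    params = ct.params
    pstr = params.to_string().encode()
    out = bytearray()
    out += _CT_MAGIC
    out += bytes([_CT_VERSION, len(pstr)])
    out += pstr
    out += struct.pack("<d", ct.log2_noise)
    out += ct.key_id.ljust(8, b"\0")[:8]
    out += ring_elem_to_bytes(params, ct.c0)
    out += ring_elem_to_bytes(params, ct.c1)
    return bytes(out)


def ct_from_bytes(data: bytes, params: RlweParams | None = None) -> Ciphertext:
    if data[:4] != _CT_MAGIC:
        raise ValueError("not a serialized ciphertext")
    version, plen = data[4], data[5]
    if version != _CT_VERSION:
        raise ValueError(f"unsupported ciphertext version {version}")
    off = 6
    pstr = data[off : off + plen].decode()
    off += plen
    parsed = RlweParams.from_string(pstr)
    if params is not None and parsed != params:
        raise ValueError("ciphertext parameters do not match")
    params = parsed
    (log2_noise,) = struct.unpack_from("<d", data, off)
    off += 8
    key_id = data[off : off + 8]
    off += 8
    size = ring_elem_size(params)
    c0 = ring_elem_from_bytes(params, data, off)
    c1 = ring_elem_from_bytes(params, data, off + size)
    return Ciphertext(c0, c1, params, log2_noise, key_id.rstrip(b"\0"))


def keypair_to_bytes(kp: HeKeyPair, include_secret: bool = True) -> bytes:
    """Serialize a keypair: params string, key id, b, a and (optionally) s."""
    pstr = kp.params.to_string().encode()
    out = bytearray()
    out += b"PVKP"
    out += bytes([_CT_VERSION, 1 if include_secret else 0, len(pstr)])
    out += pstr
    out += kp.key_id.ljust(8, b"\0")[:8]
    out += ring_elem_to_bytes(kp.params, kp.public[0])
    out += ring_elem_to_bytes(kp.params, kp.public[1])
    if include_secret:
        out += ring_elem_to_bytes(kp.params, kp.secret)
    return bytes(out)


def keypair_from_bytes(data: bytes) -> HeKeyPair:
    if data[:4] != b"PVKP":
        raise ValueError("not a serialized keypair")
    version, has_secret, plen = data[4], data[5], data[6]
    if version != _CT_VERSION:
        raise ValueError(f"unsupported keypair version {version}")
    off = 7
    params = RlweParams.from_string(data[off : off + plen].decode())
    off += plen
    key_id = data[off : off + 8].rstrip(b"\0")
    off += 8
    size = ring_elem_size(params)
    b = ring_elem_from_bytes(params, data, off)
    a = ring_elem_from_bytes(params, data, off + size)
    s = (
        ring_elem_from_bytes(params, data, off + 2 * size)
        if has_secret
        else params.ring.zero()
    )
    return HeKeyPair(params=params, public=(b, a), secret=s, key_id=key_id)
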