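"""AES-256 in counter mode, vectorized over blocks with numpy.

The at-rest layer encrypts millions of tiny (6- or 12-byte) slots, each with
its own deterministic counter block (file nonce ‖ global slot position), so
what is needed is bulk ECB encryption of arbitrary counter blocks rather than
a streaming cipher.  The implementation batches all blocks through the round
function simultaneously: S-box and xtime lookups are table indexing, ShiftRows
is a fixed byte permutation, MixColumns a handful of XORs.  Only the forward
(encrypt) direction exists — CTR mode never needs the inverse cipher.

Correctness is pinned to the published FIPS-197 and SP 800-38A test vectors
in the test suite.
"""

from __future__ import annotations

import numpy as np

# ---- tables -------------------------------------------------------------------------


def _build_sbox() -> np.ndarray:
    # multiplicative inverse in GF(2^8) followed by the affine map
    sbox = np.zeros(256, dtype=np.uint8)
    p, q = 1, 1
    first = True
    while first or p != 1:
        first = False
        # p *= 3 in GF(2^8)
        p = p ^ ((p << 1) & 0xFF) ^ (0x1B if p & 0x80 else 0)
        # q /= 3
        q ^= (q << 1) & 0xFF
        q ^= (q << 2) & 0xFF
        q ^= (q << 4) & 0xFF
        if q & 0x80:
            q ^= 0x09
        x = q ^ _rotl8(q, 1) ^ _rotl8(q, 2) ^ _rotl8(q, 3) ^ _rotl8(q, 4)
        sbox[p] = x ^ 0x63
    sbox[0] = 0x63
    return sbox


def _rotl8(x: int, n: int) -> int:
    return ((x << n) | (x >> (8 - n))) & 0xFF


SBOX = _build_sbox()
XTIME = np.array(
    [((x << 1) ^ (0x1B if x & 0x80 else 0)) & 0xFF for x in range(256)], dtype=np.uint8
)
RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36, 0x6C]

# flat byte index i = 4*c + r; ShiftRows sources byte (c+r mod 4, r)
_SHIFT = np.array([4 * (((i // 4) + (i % 4)) % 4) + (i % 4) for i in range(16)])


def expand_key(key: bytes) -> np.ndarray:
    """AES-256 key schedule → (15, 16) round-key array."""
    if len(key) != 32:
        raise ValueError("AES-256 key must be 32 bytes")
    w = [list(key[4 * i : 4 * i + 4]) for i in range(8)]
    for i in range(8, 60):
        temp = list(w[i - 1])
        if i % 8 == 0:
            temp = temp[1:] + temp[:1]
            temp = [int(SBOX[b]) for b in temp]
            temp[0] ^= RCON[i // 8 - 1]
        elif i % 8 == 4:
            temp = [int(SBOX[b]) for b in temp]
        w.append([a ^ b for a, b in zip(w[i - 8], temp)])
    flat = [b for word in w for b in word]
    return np.array(flat, dtype=np.uint8).reshape(15, 16)


def _mix_columns(state: np.ndarray) -> np.ndarray:
    # state: (N, 16) with flat index 4*c + r → view as (N, 4 columns, 4 rows)
    s = state.reshape(-1, 4, 4)
    a0, a1, a2, a3 = s[:, :, 0], s[:, :, 1], s[:, :, 2], s[:, :, 3]
    x0, x1, x2, x3 = XTIME[a0], XTIME[a1], XTIME[a2], XTIME[a3]
    out = np.empty_like(s)
    out[:, :, 0] = x0 ^ (x1 ^ a1) ^ a2 ^ a3
    out[:, :, 1] = a0 ^ x1 ^ (x2 ^ a2) ^ a3
    out[:, :, 2] = a0 ^ a1 ^ x2 ^ (x3 ^ a3)
    out[:, :, 3] = (x0 ^ a0) ^ a1 ^ a2 ^ x3
    return out.reshape(-1, 16)


def encrypt_blocks(round_keys: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """ECB-encrypt a (N, 16) uint8 array of blocks; returns (N, 16) uint8."""
    state = np.atleast_2d(np.asarray(blocks, dtype=np.uint8)) ^ round_keys[0]
    for rnd in range(1, 14):
        state = SBOX[state][:, _SHIFT]
        state = _mix_columns(state) ^ round_keys[rnd]
    state = SBOX[state][:, _SHIFT] ^ round_keys[14]
    return state


class AesCtr:
    """AES-256 keystream generator over caller-supplied counter blocks."""

    def __init__(self, key: bytes):
        self._rk = expand_key(key)

    def keystream(self, counter_blocks: np.ndarray) -> np.ndarray:
        """(N, 16) counter blocks → (N, 16) keystream bytes."""
        return encrypt_blocks(self._rk, counter_blocks)

    def xor_slots(self, counter_blocks: np.ndarray, data: np.ndarray) -> np.ndarray:
        """XOR (N, w) data (w ≤ 16) against the first w keystream bytes per block."""
        data = np.atleast_2d(np.asarray(data, dtype=np.uint8))
        ks = self.keystream(counter_blocks)
        return data ^ ks[:, : data.shape[1]]


def counter_block(nonce: int, position: int) -> bytes:
    """IV layout: 64-bit file nonce ‖ 64-bit slot position, both big-endian."""
    return nonce.to_bytes(8, "big") + position.to_bytes(8, "big")


def counter_blocks(nonce: int, positions: np.ndarray) -> np.ndarray:
    """Vectorized counter blocks for an array of slot positions."""
    positions = np.asarray(positions, dtype=np.uint64)
    out = np.empty((positions.shape[0], 16), dtype=np.uint8)
    out[:, :8] = np.frombuffer(nonce.to_bytes(8, "big"), dtype=np.uint8)
    for b in range(8):
        out[:, 8 + b] = (positions >> np.uint64(8 * (7 - b))).astype(np.uint8)
    return out
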