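"""Shared protocol plumbing: bit packing, dimension factoring, reply layout.

Both endpoints must agree byte-for-byte on how database rows are packed into
plaintext polynomials and how replies nest under recursion; that arithmetic
lives here so client and server cannot drift apart.

Packing conventions
-------------------
* Row payloads (the at-rest slot ciphertexts) are packed **slot-aligned**:
  each slot's ``slot_bytes·8`` bits are split big-endian into
  ``ceil(slot_bits / w)`` base-2^w digits, so a slot always occupies whole
  coefficients and the subtraction step's zero-run test never straddles a
  slot boundary.
* Recursion payloads (serialized ciphertexts of the previous pass) are packed
  as a plain bit stream at the full absorption width.

Absorption width
----------------
In plain mode rows are packed at the profile's D bits per coefficient.  In
subtraction mode the reply is additionally multiplied by a unit mask, which
costs up to D extra noise bits; the width D′ ≤ D is therefore chosen as the
largest value for which the scheme's own noise model still guarantees ≥ 1 bit
of budget after absorb + row summation + mask.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field

import numpy as np

from . import rlwe
from .params import SystemParams
from .rlwe import Ciphertext, Plaintext, RlweParams


# ---- dimension factoring -------------------------------------------------------------


def _iroot_ceil(value: int, k: int) -> int:
    """Smallest integer f with f**k ≥ value."""
    if value <= 1:
        return 1
    f = round(value ** (1.0 / k))
    while f**k >= value:
        f -= 1
    return f + 1


def factor_dims(n_rows: int, d: int) -> tuple[int, ...]:
    """Near-balanced factoring (n_1 ≥ … ≥ n_d, ∏ n_j ≥ n_rows) of a row count.

    n_1 = ceil(n_rows^(1/d)), then greedily for the remainder, so 9 rows at
    d=2 give (3, 3) — a query of 6 elements instead of 9.
    """
    if d not in (1, 2, 3):
        raise ValueError("dimensionality must be 1, 2 or 3 (reply grows exponentially)")
    if n_rows < 1:
        raise ValueError("need at least one row")
    dims = []
    remaining = n_rows
    for i in range(d, 0, -1):
        f = _iroot_ceil(remaining, i)
        dims.append(f)
        remaining = -(-remaining // f)
    dims = tuple(sorted(dims, reverse=True))
    assert math.prod(dims) >= n_rows
    return dims


# ---- packing -------------------------------------------------------------------------


def pack_slots(slots: np.ndarray, width: int) -> np.ndarray:
    """(N, slot_bytes) uint8 → int64 coefficients, slot-aligned at `width` bits."""
    slots = np.atleast_2d(np.asarray(slots, dtype=np.uint8))
    n, slot_bytes = slots.shape
    slot_bits = 8 * slot_bytes
    k = -(-slot_bits // width)
    bits = np.unpackbits(slots, axis=1)  # (N, slot_bits), big-endian
    padded = np.zeros((n, k * width), dtype=np.uint8)
    padded[:, k * width - slot_bits :] = bits  # left-pad each slot with zero bits
    weights = 1 << np.arange(width - 1, -1, -1, dtype=np.int64)
    return (padded.reshape(n, k, width) * weights).sum(axis=2).reshape(-1)


def unpack_slots(coeffs: np.ndarray, n_slots: int, slot_bytes: int, width: int) -> np.ndarray:
    """Inverse of pack_slots → (n_slots, slot_bytes) uint8."""
    slot_bits = 8 * slot_bytes
    k = -(-slot_bits // width)
    coeffs = np.asarray(coeffs, dtype=np.int64)[: n_slots * k].reshape(n_slots, k)
    shifts = np.arange(width - 1, -1, -1, dtype=np.int64)
    bits = ((coeffs[:, :, None] >> shifts) & 1).astype(np.uint8).reshape(n_slots, -1)
    return np.packbits(bits[:, k * width - slot_bits :], axis=1)


def pack_stream(data: bytes, width: int) -> np.ndarray:
    """Byte stream → int64 coefficients of `width` bits (big-endian bit order)."""
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    pad = (-len(bits)) % width
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    weights = 1 << np.arange(width - 1, -1, -1, dtype=np.int64)
    return (bits.reshape(-1, width) * weights).sum(axis=1)


def unpack_stream(coeffs: np.ndarray, n_bytes: int, width: int) -> bytes:
    coeffs = np.asarray(coeffs, dtype=np.int64)
    shifts = np.arange(width - 1, -1, -1, dtype=np.int64)
    bits = ((coeffs[:, None] >> shifts) & 1).astype(np.uint8).reshape(-1)
    need = 8 * n_bytes
    return np.packbits(bits[:need]).tobytes()[:n_bytes]


def coeffs_to_plaintexts(coeffs: np.ndarray, fv: RlweParams) -> list[Plaintext]:
    """Split a coefficient stream into degree-n plaintexts, zero-padding the tail."""
    n = fv.degree
    total = -(-len(coeffs) // n) * n
    buf = np.zeros(total, dtype=np.int64)
    buf[: len(coeffs)] = coeffs
    return [Plaintext(buf[i : i + n], fv) for i in range(0, total, n)]


# ---- absorption width ----------------------------------------------------------------


def absorb_width(params: SystemParams, subtract: bool | None = None) -> int:
    """Data bits per coefficient: D, or the reduced D′ in subtraction mode."""
    fv = params.fv
    if subtract is None:
        subtract = params.subtraction
    if not subtract:
        return fv.absorb_bits
    n_rows = -(-params.num_entries // params.aggregation)
    n1 = factor_dims(n_rows, params.dimensionality)[0]
    fresh = fv.fresh_noise_log2()
    sum_bits = 0.5 * math.log2(max(2, n1))
    mask_bits = math.log2(fv.t - 1)
    for w in range(fv.absorb_bits, 0, -1):
        absorb_bits = math.log2(max(math.sqrt(2), math.sqrt(fv.degree) * (2**w - 1)))
        budget = fv.budget_from_noise(fresh + absorb_bits + sum_bits + mask_bits)
        if budget >= 1.0:
            return w
    raise ValueError("no absorption width leaves noise headroom for the mask")


# ---- message objects -----------------------------------------------------------------


@dataclass
class PirQuery:
    """One encrypted one-hot selection vector per recursion dimension."""

    dims: list[list[Ciphertext]]
    subtract: bool = False

    @property
    def n_elements(self) -> int:
        return sum(len(v) for v in self.dims)

    def to_bytes(self) -> bytes:
        out = bytearray(b"PVQ1")
        out += struct.pack("<BB", len(self.dims), 1 if self.subtract else 0)
        for vec in self.dims:
            out += struct.pack("<I", len(vec))
            for ct in vec:
                blob = rlwe.ct_to_bytes(ct)
                out += struct.pack("<I", len(blob)) + blob
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "PirQuery":
        if data[:4] != b"PVQ1":
            raise ValueError("not a serialized PIR query")
        nd, sub = struct.unpack_from("<BB", data, 4)
        off = 6
        dims = []
        for _ in range(nd):
            (ln,) = struct.unpack_from("<I", data, off)
            off += 4
            vec = []
            for _ in range(ln):
                (sz,) = struct.unpack_from("<I", data, off)
                off += 4
                vec.append(rlwe.ct_from_bytes(data[off : off + sz]))
                off += sz
            dims.append(vec)
        return cls(dims, bool(sub))


@dataclass
class SubQuery:
    """Replicated slot-ciphertexts of the candidate digest, packed per chunk."""

    chunks: list[Plaintext]
    slot_bytes: int
    width: int

    def to_bytes(self) -> bytes:
        out = bytearray(b"PVS1")
        out += struct.pack("<BBH", self.slot_bytes, self.width, len(self.chunks))
        for c in self.chunks:
            out += struct.pack("<I", len(c.coeffs))
            out += c.coeffs.astype("<i8").tobytes()
        return bytes(out)


@dataclass
class PirReply:
    """Ciphertexts covering one (aggregated) row's packed payload."""

    cts: list[Ciphertext]
    masked: bool = False

    def to_bytes(self) -> bytes:
        out = bytearray(b"PVR1")
        out += struct.pack("<BH", 1 if self.masked else 0, len(self.cts))
        for ct in self.cts:
            blob = rlwe.ct_to_bytes(ct)
            out += struct.pack("<I", len(blob)) + blob
        return bytes(out)


# ---- reply layout --------------------------------------------------------------------


@dataclass(frozen=True)
class ReplyLayout:
    """Deterministic shape of the protocol messages for one store."""

    n_rows: int  # aggregated rows (before padding to the grid)
    dims: tuple[int, ...]
    row_size: int  # effective slots per bucket
    slots_per_row: int  # aggregation · row_size
    width: int  # data bits/coefficient at the innermost pass
    coeffs_per_slot: int
    chunk_counts: tuple[int, ...]  # ciphertexts produced by pass 1 .. d

    @classmethod
    def plan(
        cls, params: SystemParams, row_size: int | None = None, subtract: bool | None = None
    ) -> "ReplyLayout":
        if row_size is None:
            row_size = params.row_size
        if subtract is None:
            subtract = params.subtraction
        fv = params.fv
        n_rows = -(-params.num_entries // params.aggregation)
        dims = factor_dims(n_rows, params.dimensionality)
        width = absorb_width(params, subtract)
        slots = params.aggregation * row_size
        k = -(-(8 * params.slot_bytes) // width)
        chunks = [-(-(slots * k) // fv.degree)]
        ct_size = rlwe.serialized_size(fv)
        for _ in range(1, len(dims)):
            n_bytes = chunks[-1] * ct_size
            coeffs = -(-(8 * n_bytes) // fv.absorb_bits)
            chunks.append(-(-coeffs // fv.degree))
        return cls(
            n_rows=n_rows,
            dims=dims,
            row_size=row_size,
            slots_per_row=slots,
            width=width,
            coeffs_per_slot=k,
            chunk_counts=tuple(chunks),
        )

    @property
    def query_elements(self) -> int:
        return sum(self.dims)

    @property
    def reply_ciphertexts(self) -> int:
        return self.chunk_counts[-1]

    def row_coordinates(self, row: int) -> tuple[int, ...]:
        """Mixed-radix coordinates of a row in the grid (first dim most significant)."""
        coords = []
        for n_j in reversed(self.dims):
            coords.append(row % n_j)
            row //= n_j
        return tuple(reversed(coords))
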