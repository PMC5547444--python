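"""Per-patient bucketed hash store: placement, padding, at-rest encryption.

Each variant's truncated keyed digest lands in the bucket selected by the
first x bits of the digest; colliding digests are concatenated within the
bucket.  Every row is padded to a fixed slot count — in strong mode the
global capacity `row_size` (store size then reveals nothing about the variant
count), in weak mode the per-file maximum load (smaller, but leaks an
approximate count, recorded in the header).  Dummy slots carry the dummy
count in every byte (PKCS#7 style), taken mod 256 so large counts stay
well-defined.

Every slot is encrypted independently under AES-256-CTR with
IV = file nonce (64 bits) ‖ global slot position (64 bits), where the global
position is ``bucket_index · row_size + slot``.  One full counter block is
spent per slot, which makes any slot's ciphertext recomputable in isolation —
the equality contract the subtraction step depends on.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aes import AesCtr, counter_blocks
from .codec import HashedVariant, VariantKey, hash_and_map
from .params import KeyMaterial, SystemParams

_STORE_MAGIC = b"PIRVCF01"


class BucketCapacityError(ValueError):
    def __init__(self, bucket: int, load: int, row_size: int):
        super().__init__(
            f"bucket {bucket} holds {load} variants, exceeding row_size {row_size}"
        )
        self.bucket = bucket
        self.load = load
        self.row_size = row_size


def bucketize(
    hashes: Iterable[HashedVariant], params: SystemParams
) -> list[list[bytes]]:
    """Place digests into 2^x buckets in insertion order; duplicates stored once."""
    buckets: list[list[bytes]] = [[] for _ in range(params.num_entries)]
    seen: list[set] = [set() for _ in range(params.num_entries)]
    slot_bytes = params.slot_bytes
    for hv in hashes:
        if len(hv.digest) != slot_bytes:
            raise ValueError("digest length does not match data_hash_size")
        b = hv.bucket_index
        if hv.digest not in seen[b]:
            seen[b].add(hv.digest)
            buckets[b].append(hv.digest)
    if params.padding_mode == "strong":
        for b, row in enumerate(buckets):
            if len(row) > params.row_size:
                raise BucketCapacityError(b, len(row), params.row_size)
    return buckets


def dummy_slot(count: int, slot_bytes: int) -> bytes:
    """A padding slot: the dummy count (mod 256) repeated across the slot."""
    return bytes([count % 256]) * slot_bytes


def pad_row(row: Sequence[bytes], row_size: int, slot_bytes: int) -> list[bytes]:
    """Append dummy slots so the row has exactly `row_size` slots."""
    if len(row) > row_size:
        raise ValueError(f"row holds {len(row)} slots, exceeding row_size {row_size}")
    n_dummy = row_size - len(row)
    return list(row) + [dummy_slot(n_dummy, slot_bytes)] * n_dummy


def unpad_row(slots: Sequence[bytes], row_size: int) -> list[bytes]:
    """Strip the dummy suffix of a decrypted row (inverse of pad_row).

    The dummy count is read (mod 256) from the trailing slot; when the row is
    longer than 256 slots the count is disambiguated by taking the largest
    candidate whose whole suffix matches the dummy pattern.
    """
    slots = list(slots)
    if len(slots) != row_size:
        raise ValueError("row must be padded to row_size before unpadding")
    c = slots[-1][0]
    candidates = [n for n in range(c if c else 256, row_size + 1, 256)]
    for count in reversed(candidates):
        pattern = dummy_slot(count, len(slots[-1]))
        if all(s == pattern for s in slots[row_size - count :]):
            return slots[: row_size - count]
    return slots


@dataclass
class EncodedFile:
    """One patient's padded, at-rest-encrypted hash store."""

    file_id: str
    nonce: int
    params: SystemParams
    row_size: int  # effective slots/row (== params.row_size in strong mode)
    variant_count: int  # I; only serialized in weak mode
    data: np.ndarray  # (num_entries, row_size, slot_bytes) uint8, ciphertext

    @property
    def payload_bytes(self) -> int:
        return int(self.data.size)

    # ---- binary format ---------------------------------------------------------
    def to_bytes(self) -> bytes:
        header = {
            "params": self.params.to_dict(),
            "file_id": self.file_id,
            "nonce": f"{self.nonce:016x}",  # fixed width: header length must not vary
            "row_size": self.row_size,
        }
        if self.params.padding_mode == "weak":
            header["variant_count"] = self.variant_count
        hb = json.dumps(header).encode()
        return _STORE_MAGIC + struct.pack("<I", len(hb)) + hb + self.data.tobytes()

    @classmethod
    def from_bytes(cls, blob: bytes) -> "EncodedFile":
        if blob[:8] != _STORE_MAGIC:
            raise ValueError("not an encoded store (bad magic)")
        (hlen,) = struct.unpack_from("<I", blob, 8)
        header = json.loads(blob[12 : 12 + hlen].decode())
        params = SystemParams.from_dict(header["params"])
        row_size = header["row_size"]
        data = np.frombuffer(blob, dtype=np.uint8, offset=12 + hlen).reshape(
            params.num_entries, row_size, params.slot_bytes
        )
        return cls(
            file_id=header["file_id"],
            nonce=int(header["nonce"], 16),
            params=params,
            row_size=row_size,
            variant_count=header.get("variant_count", -1),
            data=data.copy(),
        )


def _slot_positions(num_entries: int, row_size: int) -> np.ndarray:
    return np.arange(num_entries * row_size, dtype=np.uint64)


def encrypt_at_rest(
    buckets: list[list[bytes]],
    keys: KeyMaterial,
    nonce: int,
    params: SystemParams,
    file_id: str = "",
    variant_count: int | None = None,
) -> EncodedFile:
    """Pad every bucket and encrypt each slot under its positional counter block."""
    slot_bytes = params.slot_bytes
    if params.padding_mode == "strong":
        row_size = params.row_size
    else:
        row_size = max(1, max((len(r) for r in buckets), default=1))
    n_variants = (
        variant_count
        if variant_count is not None
        else sum(len(r) for r in buckets)
    )
    plain = np.empty((params.num_entries, row_size, slot_bytes), dtype=np.uint8)
    for b, row in enumerate(buckets):
        padded = pad_row(row, row_size, slot_bytes)
        plain[b] = np.frombuffer(b"".join(padded), dtype=np.uint8).reshape(
            row_size, slot_bytes
        )
    cipher = AesCtr(keys.sym_key)
    blocks = counter_blocks(nonce, _slot_positions(params.num_entries, row_size))
    data = cipher.xor_slots(blocks, plain.reshape(-1, slot_bytes)).reshape(plain.shape)
    return EncodedFile(
        file_id=file_id,
        nonce=nonce,
        params=params,
        row_size=row_size,
        variant_count=n_variants,
        data=data,
    )


def decrypt_at_rest(encoded: EncodedFile, keys: KeyMaterial) -> np.ndarray:
    """Inverse of encrypt_at_rest: the padded plaintext bucket array."""
    cipher = AesCtr(keys.sym_key)
    blocks = counter_blocks(
        encoded.nonce, _slot_positions(encoded.params.num_entries, encoded.row_size)
    )
    slot_bytes = encoded.params.slot_bytes
    return cipher.xor_slots(blocks, encoded.data.reshape(-1, slot_bytes)).reshape(
        encoded.data.shape
    )


def slot_ciphertext(
    sym_key: bytes,
    nonce: int,
    bucket: int,
    slot: int,
    digest: bytes,
    row_size: int,
    num_entries: int | None = None,
) -> bytes:
    """The exact bytes encrypt_at_rest would place at (bucket, slot) for `digest`.

    This is the client-side primitive behind the subtract query: the stored
    ciphertext of a digest is recomputable from (S, nonce, position) alone.
    """
    if slot < 0 or slot >= row_size or bucket < 0:
        raise ValueError("slot position out of range")
    if num_entries is not None and bucket >= num_entries:
        raise ValueError("bucket index out of range")
    position = bucket * row_size + slot
    cipher = AesCtr(sym_key)
    blocks = counter_blocks(nonce, np.array([position], dtype=np.uint64))
    data = np.frombuffer(digest, dtype=np.uint8).reshape(1, -1)
    return cipher.xor_slots(blocks, data)[0].tobytes()


def build_store(
    variants: Iterable[VariantKey],
    keys: KeyMaterial,
    params: SystemParams,
    file_id: str = "",
    nonce: int | None = None,
    rng=None,
) -> EncodedFile:
    """Hash, bucketize, pad and encrypt a sequence of variants in one call."""
    hashes = [
        hash_and_map(v, keys.mac_key, params.data_hash_size, params.bits_for_mapping)
        for v in variants
    ]
    buckets = bucketize(hashes, params)
    if nonce is None:
        nonce = keys.fresh_nonce(rng)
    else:
        keys.register_nonce(nonce)
    return encrypt_at_rest(buckets, keys, nonce, params, file_id=file_id)
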