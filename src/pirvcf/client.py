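"""PIR client: query construction, sub-queries, reply extraction.

The client knows the keys (S, U, R/r) and the store's shape.  For a variant
it computes the keyed digest, maps the hash prefix to a bucket, addresses the
aggregated row holding that bucket, and emits one encrypted one-hot vector
per recursion dimension.  Replies unwind in reverse: the outermost ciphertexts
decrypt to the serialization of the previous pass, down to the innermost row
payload, which is either symmetrically decrypted and compared (plain mode) or
scanned for a slot-aligned run of zero coefficients (subtraction mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import rlwe
from .codec import VariantKey, hash_and_map
from .params import KeyMaterial, SystemParams
from .protocol import (
    PirQuery,
    PirReply,
    ReplyLayout,
    SubQuery,
    coeffs_to_plaintexts,
    pack_slots,
    unpack_slots,
    unpack_stream,
)
from .rlwe import Plaintext
from .store import EncodedFile, slot_ciphertext, unpad_row


@dataclass(frozen=True)
class StoreHandle:
    """What the client must remember about one uploaded store."""

    file_id: str
    nonce: int
    row_size: int

    @classmethod
    def of(cls, encoded: EncodedFile) -> "StoreHandle":
        return cls(encoded.file_id, encoded.nonce, encoded.row_size)


@dataclass
class QueryResult:
    present: bool
    digest: bytes
    bucket: int
    row: int
    mode: str
    matched_slot: int | None = None
    extra_digests: list[bytes] = field(default_factory=list)


class PirClient:
    def __init__(self, keys: KeyMaterial, params: SystemParams, rng=None):
        self.keys = keys
        self.params = params
        self._rng = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )

    # ---- targeting -------------------------------------------------------------
    def target(self, v: VariantKey) -> tuple[bytes, int, int]:
        """(digest, bucket, aggregated row) for a variant."""
        p = self.params
        hv = hash_and_map(v, self.keys.mac_key, p.data_hash_size, p.bits_for_mapping)
        return hv.digest, hv.bucket_index, hv.bucket_index // p.aggregation

    # ---- query construction ------------------------------------------------------
    def make_query(
        self, v: VariantKey, store: StoreHandle, subtract: bool | None = None
    ) -> tuple[PirQuery, int]:
        """Encrypted one-hot selectors for the variant's aggregated row."""
        layout = ReplyLayout.plan(self.params, store.row_size, subtract)
        _, _, row = self.target(v)
        coords = layout.row_coordinates(row)
        pk = self.keys.he_keys
        dims = []
        for n_j, i_j in zip(layout.dims, coords):
            vec = [
                rlwe.encrypt(pk, 1 if l == i_j else 0, self._rng) for l in range(n_j)
            ]
            dims.append(vec)
        sub = self.params.subtraction if subtract is None else subtract
        return PirQuery(dims, subtract=sub), row

    def make_sub_query(
        self, v: VariantKey, store: StoreHandle, target_row: int,
        subtract: bool = True,
    ) -> SubQuery:
        """The candidate digest's slot ciphertexts, replicated across the row.

        Slot s of bucket b would store E_S(digest) under the counter block of
        global position b·row_size + s; the sub query reproduces those exact
        bytes for every slot of the aggregated target row.
        """
        p = self.params
        layout = ReplyLayout.plan(p, store.row_size, subtract)
        digest, _, _ = self.target(v)
        slots = []
        for a in range(p.aggregation):
            bucket = target_row * p.aggregation + a
            for s in range(store.row_size):
                if bucket < p.num_entries:
                    slots.append(
                        slot_ciphertext(
                            self.keys.sym_key, store.nonce, bucket, s, digest,
                            store.row_size, p.num_entries,
                        )
                    )
                else:  # grid padding beyond the last bucket
                    slots.append(bytes(p.slot_bytes))
        arr = np.frombuffer(b"".join(slots), dtype=np.uint8).reshape(
            -1, p.slot_bytes
        )
        coeffs = pack_slots(arr, layout.width)
        chunks = coeffs_to_plaintexts(coeffs, p.fv)
        return SubQuery(chunks=chunks, slot_bytes=p.slot_bytes, width=layout.width)

    # ---- reply extraction ----------------------------------------------------------
    def _unwind(self, reply: PirReply, layout: ReplyLayout) -> np.ndarray:
        """Peel recursion layers; returns the innermost coefficient stream."""
        sk = self.keys.he_keys
        fv = self.params.fv
        cts = reply.cts
        ct_size = rlwe.serialized_size(fv)
        for level in range(len(layout.chunk_counts) - 1, 0, -1):
            coeffs = np.concatenate([rlwe.decrypt(sk, ct).coeffs for ct in cts])
            n_bytes = layout.chunk_counts[level - 1] * ct_size
            blob = unpack_stream(coeffs, n_bytes, fv.absorb_bits)
            cts = [
                rlwe.ct_from_bytes(blob[i * ct_size : (i + 1) * ct_size])
                for i in range(layout.chunk_counts[level - 1])
            ]
        return np.concatenate([rlwe.decrypt(sk, ct).coeffs for ct in cts])

    def extract_reply(
        self,
        reply: PirReply,
        v: VariantKey,
        store: StoreHandle,
        subtract: bool | None = None,
    ) -> QueryResult:
        p = self.params
        if subtract is None:
            subtract = reply.masked
        layout = ReplyLayout.plan(p, store.row_size, subtract)
        digest, bucket, row = self.target(v)
        coeffs = self._unwind(reply, layout)
        k = layout.coeffs_per_slot
        n_slots = layout.slots_per_row

        if reply.masked:
            per_slot = coeffs[: n_slots * k].reshape(n_slots, k)
            zero_slots = np.flatnonzero((per_slot == 0).all(axis=1))
            matched = int(zero_slots[0]) if zero_slots.size else None
            return QueryResult(
                present=bool(zero_slots.size),
                digest=digest,
                bucket=bucket,
                row=row,
                mode="subtract",
                matched_slot=matched,
            )

        # plain mode: recover the row's at-rest bytes and decrypt each slot
        slots = unpack_slots(coeffs, n_slots, p.slot_bytes, layout.width)
        present = False
        matched = None
        extras: list[bytes] = []
        for a in range(p.aggregation):
            b = row * p.aggregation + a
            if b >= p.num_entries:
                continue
            plains = []
            for s in range(store.row_size):
                idx = a * store.row_size + s
                raw = slots[idx].tobytes()
                expected = slot_ciphertext(
                    self.keys.sym_key, store.nonce, b, s, digest,
                    store.row_size, p.num_entries,
                )
                # stored plaintext = raw ⊕ keystream, keystream = expected ⊕ digest
                plains.append(bytes(x ^ y ^ z for x, y, z in zip(raw, expected, digest)))
                if raw == expected:
                    present = True
                    matched = idx
            extras.extend(
                d for d in unpad_row(plains, store.row_size) if d != digest
            )
        return QueryResult(
            present=present,
            digest=digest,
            bucket=bucket,
            row=row,
            mode="plain",
            matched_slot=matched,
            extra_digests=extras,
        )

    # ---- convenience ---------------------------------------------------------------
    def search(
        self,
        server,
        store: StoreHandle,
        v: VariantKey,
        subtract: bool | None = None,
    ) -> QueryResult:
        """Full round trip against an in-process server."""
        sub_mode = self.params.subtraction if subtract is None else subtract
        query, row = self.make_query(v, store, sub_mode)
        sub = (
            self.make_sub_query(v, store, row, sub_mode) if sub_mode else None
        )
        reply = server.reply_generate(store.file_id, query, sub)
        return self.extract_reply(reply, v, store, sub_mode)
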