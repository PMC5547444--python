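"""Oblivious PIR server: absorption dot-products, recursion, subtraction step.

The server holds imported stores as packed plaintext polynomials.  Reply
generation touches every row exactly once per dimension pass — the operation
count is a function of the database shape alone, never of the target — which
is the obliviousness the retrieval protocol rests on.  The server never
decrypts anything: it only absorbs its (symmetrically encrypted) rows into
the client's homomorphic ciphertexts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import rlwe
from .params import SystemParams
from .protocol import (
    PirQuery,
    PirReply,
    ReplyLayout,
    SubQuery,
    coeffs_to_plaintexts,
    pack_slots,
    pack_stream,
)
from .rlwe import Ciphertext, Plaintext, PlaintextNtt
from .store import EncodedFile


@dataclass
class ImportedStore:
    """A store pre-packed into NTT-domain plaintext chunks, grid-padded."""

    file_id: str
    params: SystemParams
    layout: ReplyLayout
    rows: list[list[PlaintextNtt]]  # ∏ dims rows × chunk_counts[0] chunks


def import_store(
    encoded: EncodedFile, subtract: bool | None = None
) -> ImportedStore:
    """Pack each aggregated row's slot ciphertexts into plaintext polynomials."""
    params = encoded.params
    fv = params.fv
    layout = ReplyLayout.plan(params, row_size=encoded.row_size, subtract=subtract)
    alpha = params.aggregation
    slot_bytes = params.slot_bytes
    data = encoded.data.reshape(params.num_entries, encoded.row_size, slot_bytes)
    rows: list[list[PlaintextNtt]] = []
    zero_chunk = None
    for r in range(layout.n_rows):
        slots = data[r * alpha : (r + 1) * alpha].reshape(-1, slot_bytes)
        if slots.shape[0] < layout.slots_per_row:
            # trailing aggregated row of a num_entries not divisible by α
            pad = np.zeros(
                (layout.slots_per_row - slots.shape[0], slot_bytes), dtype=np.uint8
            )
            slots = np.concatenate([slots, pad])
        coeffs = pack_slots(slots, layout.width)
        chunks = [PlaintextNtt(p) for p in coeffs_to_plaintexts(coeffs, fv)]
        if len(chunks) != layout.chunk_counts[0]:
            raise ValueError("row length mismatch against the planned layout")
        rows.append(chunks)
    grid = math.prod(layout.dims)
    if grid > len(rows):
        if zero_chunk is None:
            zero_chunk = PlaintextNtt(Plaintext.zero(fv))
        rows.extend(
            [[zero_chunk] * layout.chunk_counts[0] for _ in range(grid - len(rows))]
        )
    return ImportedStore(
        file_id=encoded.file_id, params=params, layout=layout, rows=rows
    )


class PirServer:
    """Holds imported stores and answers queries without learning the target."""

    def __init__(self, rng=None):
        self._stores: dict[str, ImportedStore] = {}
        self._rng = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        self.op_counts: dict[str, int] = {}

    def add_store(self, encoded: EncodedFile, subtract: bool | None = None) -> None:
        imported = import_store(encoded, subtract=subtract)
        self._stores[imported.file_id] = imported

    def store_ids(self) -> list[str]:
        return sorted(self._stores)

    def _reset_counts(self):
        self.op_counts = {"absorb": 0, "add": 0, "sub_plain": 0, "mask": 0}

    # ---- reply generation ------------------------------------------------------------
    def reply_generate(
        self, file_id: str, query: PirQuery, sub: SubQuery | None = None
    ) -> PirReply:
        """Absorb every row into the query, recursing over the grid dimensions.

        With `sub` present, the innermost replies are subtracted against the
        replicated candidate slot-ciphertexts and masked by per-ciphertext
        random units before recursion continues (the subtraction step).
        """
        imported = self._stores[file_id]
        layout = imported.layout
        fv = imported.params.fv
        if tuple(len(v) for v in query.dims) != layout.dims:
            raise ValueError(
                f"query dims {tuple(len(v) for v in query.dims)} do not match "
                f"database factoring {layout.dims}"
            )
        if sub is not None and len(sub.chunks) != layout.chunk_counts[0]:
            raise ValueError("subtract query length does not match a database row")
        self._reset_counts()

        rows = imported.rows
        replies = self._pass(query.dims[0], rows)
        if sub is not None:
            sub_ntt = [PlaintextNtt(p) for p in sub.chunks]
            replies = [self._subtract_and_mask(row, sub_ntt) for row in replies]
        for dim_vec in query.dims[1:]:
            next_rows = [self._repack(row_cts, fv) for row_cts in replies]
            replies = self._pass(dim_vec, next_rows)
        assert len(replies) == 1
        return PirReply(replies[0], masked=sub is not None)

    def _pass(
        self, dim_vec: list[Ciphertext], rows: list[list[PlaintextNtt]]
    ) -> list[list[Ciphertext]]:
        """One recursion pass: Σ_i q[i] · row[i·m + j] for every group j."""
        n_i = len(dim_vec)
        m = len(rows) // n_i
        n_chunks = len(rows[0])
        out: list[list[Ciphertext]] = []
        for j in range(m):
            acc: list[Ciphertext | None] = [None] * n_chunks
            for i in range(n_i):
                row = rows[i * m + j]
                for c in range(n_chunks):
                    term = rlwe.absorb(dim_vec[i], row[c])
                    self.op_counts["absorb"] += 1
                    if acc[c] is None:
                        acc[c] = term
                    else:
                        acc[c] = rlwe.add(acc[c], term)
                        self.op_counts["add"] += 1
            out.append(acc)  # type: ignore[arg-type]
        return out

    def _subtract_and_mask(
        self, reply_row: list[Ciphertext], sub_ntt: list[PlaintextNtt]
    ) -> list[Ciphertext]:
        """reply′ = mask ∘ (reply − sub): zero coefficients (a matching slot)
        survive, everything else is multiplied by a fresh random odd unit."""
        t = reply_row[0].params.t
        out = []
        for ct, p in zip(reply_row, sub_ntt):
            diff = rlwe.sub_plain(ct, p)
            self.op_counts["sub_plain"] += 1
            u = int(self._rng.integers(0, t // 2)) * 2 + 1
            out.append(rlwe.scalar_mask(diff, u))
            self.op_counts["mask"] += 1
        return out

    @staticmethod
    def _repack(row_cts: list[Ciphertext], fv) -> list[PlaintextNtt]:
        """Serialize a pass-j reply row into plaintext chunks for pass j+1."""
        blob = b"".join(rlwe.ct_to_bytes(ct) for ct in row_cts)
        coeffs = pack_stream(blob, fv.absorb_bits)
        return [PlaintextNtt(p) for p in coeffs_to_plaintexts(coeffs, fv)]
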