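"""Parameter planning: collision statistics, error rates, sizing, shapes.

Everything here is closed-form arithmetic or a short balls-into-bins
simulation; the recommender scores candidate profiles by a communication
model (total serialized query + reply bytes), not by wall-clock timing,
which is hardware-bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import rlwe
from .params import SystemParams
from .protocol import ReplyLayout, factor_dims


def fp_probability(data_hash_size: int, n_variants: int) -> float:
    """Union-bound false-positive probability of a truncated-hash membership test.

    With 48-bit digests and five million stored variants this is
    5e6 / 2^48 ≈ 2^-25 — far below DNA-sequencing error rates.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be ≥ 1")
    return n_variants / float(1 << data_hash_size)


def expected_max_load(
    n_variants: int, x: int, n_trials: int = 10, seed: int | None = None
) -> float:
    """Mean (over trials) maximum bucket occupancy of n uniform throws into 2^x bins.

    The uniformity of the keyed hash makes bucket placement a classical
    balls-into-bins process; for five million variants and x = 13 the mean
    maximum load sits around 710, which motivates the default row capacity
    of 716.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be ≥ 1")
    n_buckets = 1 << x
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_trials)
    for trial in range(n_trials):
        idx = rng.integers(0, n_buckets, n_variants)
        maxima[trial] = np.bincount(idx, minlength=n_buckets).max()
    return float(maxima.mean())


@dataclass(frozen=True)
class StoreSize:
    padded_bytes: int
    raw_bytes: int | None

    @property
    def padded_mb(self) -> float:
        """Decimal megabytes (10^6 bytes), the unit used throughout the reports."""
        return self.padded_bytes / 1e6

    @property
    def raw_mb(self) -> float | None:
        return None if self.raw_bytes is None else self.raw_bytes / 1e6


def store_size(params: SystemParams, n_variants: int | None = None) -> StoreSize:
    """Padded store payload (num_entries·row_size·hash bytes) and raw payload."""
    padded = params.num_entries * params.row_size * params.slot_bytes
    raw = None if n_variants is None else n_variants * params.slot_bytes
    return StoreSize(padded_bytes=padded, raw_bytes=raw)


@dataclass(frozen=True)
class QueryReplyShape:
    dims: tuple[int, ...]
    query_elements: int
    reply_ciphertexts: int
    query_bytes: int
    reply_bytes: int
    sub_query_bytes: int
    expansion_per_pass: tuple[float, ...]

    @property
    def transfer_bytes(self) -> int:
        return self.query_bytes + self.reply_bytes + self.sub_query_bytes


def query_reply_shape(
    params: SystemParams, row_size: int | None = None
) -> QueryReplyShape:
    """Serialized query/reply shape implied by a profile (communication model)."""
    layout = ReplyLayout.plan(params, row_size)
    ct_size = rlwe.serialized_size(params.fv)
    expansion = tuple(
        layout.chunk_counts[i + 1] / layout.chunk_counts[i]
        for i in range(len(layout.chunk_counts) - 1)
    )
    sub_bytes = 0
    if params.subtraction:
        # one packed plaintext row: coefficients at 8 bytes apiece
        sub_bytes = layout.chunk_counts[0] * params.fv.degree * 8
    return QueryReplyShape(
        dims=layout.dims,
        query_elements=layout.query_elements,
        reply_ciphertexts=layout.reply_ciphertexts,
        query_bytes=layout.query_elements * ct_size,
        reply_bytes=layout.reply_ciphertexts * ct_size,
        sub_query_bytes=sub_bytes,
        expansion_per_pass=expansion,
    )


def recommend(
    candidates: list[SystemParams],
    n_variants: int,
    seed: int | None = 0,
    n_trials: int = 3,
) -> SystemParams:
    """Pick the candidate minimizing modeled transfer bytes, subject to capacity.

    Feasibility: strong-padding profiles must satisfy
    row_size ≥ expected max bucket load for `n_variants`; ties break toward
    the smaller reply, then candidate order.  Raises when nothing fits.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    load_cache: dict[int, float] = {}
    scored = []
    for rank, cand in enumerate(candidates):
        if cand.padding_mode == "strong":
            x = cand.bits_for_mapping
            if x not in load_cache:
                load_cache[x] = expected_max_load(n_variants, x, n_trials, seed)
            if cand.row_size < load_cache[x]:
                continue
        shape = query_reply_shape(cand)
        scored.append((shape.transfer_bytes, shape.reply_bytes, rank, cand))
    if not scored:
        raise ValueError(
            f"no candidate has enough row capacity for {n_variants} variants"
        )
    scored.sort(key=lambda s: s[:3])
    return scored[0][3]


def plan_report(
    profiles: dict[str, SystemParams], n_variants: int | None = None
):
    """Tabular (pandas) summary of the hardware-independent planning columns."""
    import pandas as pd

    rows = []
    for name, p in profiles.items():
        shape = query_reply_shape(p)
        size = store_size(p, n_variants)
        rows.append(
            {
                "profile": name,
                "data_hash_size": p.data_hash_size,
                "x": p.bits_for_mapping,
                "num_entries": p.num_entries,
                "row_size": p.row_size,
                "encryption_mode": p.fv.to_string(),
                "aggregation": p.aggregation,
                "dimensionality": "%d (%s)"
                % (p.dimensionality, "x".join(map(str, shape.dims))),
                "store_mb": round(size.padded_mb, 2),
                "raw_mb": None if size.raw_mb is None else round(size.raw_mb, 2),
                "query_elements": shape.query_elements,
                "reply_ciphertexts": shape.reply_ciphertexts,
                "transfer_mb": round(shape.transfer_bytes / 1e6, 2),
                "fp_prob_log2": (
                    None
                    if n_variants is None
                    else round(math.log2(fp_probability(p.data_hash_size, n_variants)), 1)
                ),
            }
        )
    return pd.DataFrame(rows)
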