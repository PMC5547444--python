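"""Deterministic synthetic VCF generation for fixtures and scale tests.

Positions are drawn uniformly within per-chromosome bounds: the encoding and
retrieval statistics depend only on the uniformity of the keyed hash, so the
empirical density of real variant calls is irrelevant to correctness (what
this deliberately does not emulate: allele frequencies, linkage, clustering
of calls).  SNPs and short indels are mixed 9:1.  Output is byte-identical
for a given (n, seed, weights) triple.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .codec import VariantKey

# GRCh38 primary-assembly chromosome lengths; every chromosome is shorter
# than 2^28, so generated positions always fit the 28-bit encoding field
CHROM_LENGTHS: dict[str, int] = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468, "X": 156040895, "Y": 57227415,
}
_POS_CAP = (1 << 28) - 1  # keep positions encodable in 28 bits
_BASES = np.array(list("ACGT"))
_HEADER = "##fileformat=VCFv4.2\n##source=pirvcf-synth\n"
_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _alt_base(rng: np.random.Generator, ref: np.ndarray) -> np.ndarray:
    """A base different from ref, vectorized."""
    shift = rng.integers(1, 4, ref.shape[0])
    ref_idx = np.searchsorted(_BASES, ref)
    return _BASES[(ref_idx + shift) % 4]


def generate(
    n_variants: int,
    seed: int = 0,
    chrom_weights: dict[str, float] | None = None,
    out=None,
) -> str:
    """Produce VCF text with n unique (CHROM, POS, REF, ALT) variant records.

    9 of 10 records are SNPs; the rest are short (1–5 bp) insertions or
    deletions.  `chrom_weights` defaults to weights proportional to
    chromosome length.  When `out` is given the text is also written there.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be ≥ 0")
    rng = np.random.default_rng(seed)
    chroms = list(CHROM_LENGTHS)
    if chrom_weights is None:
        w = np.array([CHROM_LENGTHS[c] for c in chroms], dtype=float)
    else:
        chroms = list(chrom_weights)
        w = np.array([chrom_weights[c] for c in chroms], dtype=float)
    w = w / w.sum()
    caps = np.array([min(CHROM_LENGTHS.get(c, _POS_CAP), _POS_CAP) for c in chroms])

    records: list[tuple[int, int, str, str]] = []  # (chrom idx, pos, ref, alt)
    seen: set[tuple[int, int]] = set()
    while len(records) < n_variants:
        want = n_variants - len(records)
        batch = max(64, int(want * 1.2))
        ci = rng.choice(len(chroms), size=batch, p=w)
        pos = (rng.random(batch) * (caps[ci] - 1)).astype(np.int64) + 1
        ref = _BASES[rng.integers(0, 4, batch)]
        alt = _alt_base(rng, ref)
        kind = rng.random(batch)  # < .9 SNP, < .95 insertion, else deletion
        indel_len = rng.integers(1, 6, batch)
        extra = _BASES[rng.integers(0, 4, (batch, 5))]
        for i in range(batch):
            if len(records) >= n_variants:
                break
            key = (int(ci[i]), int(pos[i]))
            if key in seen:
                continue
            seen.add(key)
            r, a = str(ref[i]), str(alt[i])
            if kind[i] >= 0.95:
                r = r + "".join(extra[i, : indel_len[i]])
                a = r[0]
            elif kind[i] >= 0.90:
                a = r + "".join(extra[i, : indel_len[i]])
            records.append((int(ci[i]), int(pos[i]), r, a))

    records.sort(key=lambda t: (t[0], t[1]))
    lines = [_HEADER]
    lines += [f"##contig=<ID={c},length={CHROM_LENGTHS[c]}>\n" for c in chroms if c in CHROM_LENGTHS]
    lines.append(_COLUMNS)
    lines += [
        f"{chroms[ci]}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n"
        for ci, pos, ref, alt in records
    ]
    text = "".join(lines)
    if out is not None:
        Path(out).write_text(text)
    return text


def generate_keys(
    n_variants: int, seed: int = 0, chrom_weights: dict[str, float] | None = None
) -> list[VariantKey]:
    """Like generate() but returning parsed VariantKey objects directly."""
    from .codec import parse_vcf

    return list(parse_vcf(io.StringIO(generate(n_variants, seed, chrom_weights))))
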