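"""Variant parsing, canonical serialization, keyed hashing and bucket mapping.

A genomic variant is identified by four parameters — chromosome, 1-based
position, reference allele, alternate allele.  Each variant is serialized
canonically, MAC'd with HMAC-SHA256 under the owner's hashing key U, truncated
to ``data_hash_size`` bits, and the first ``x`` bits of that digest select the
bucket index in the encoded store.

VCF body records are read by a tolerant line reader so that malformed records
can be skipped (with a logged warning and a counter) instead of aborting the
whole file; the test suite cross-checks the reader against cyvcf2 on fixture
files.
"""

from __future__ import annotations

import gzip
import hashlib
import hmac
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_CHROM_CODES = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def normalize_chrom(label: str) -> str:
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    label = label.upper()
    return "MT" if label == "M" else label


@dataclass(frozen=True)
class VariantKey:
    """The four parameters that identify a variant in a VCF body record."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.position < 1:
            raise ValueError("position must be ≥ 1 (1-based, as in VCF POS)")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if not (_BASES.issuperset(self.ref) and _BASES.issuperset(self.alt)):
            raise ValueError(f"alleles must be over A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class HashedVariant:
    """Truncated keyed digest plus the bucket index its prefix maps to."""

    digest: bytes
    bucket_index: int


class VcfParseResult(list):
    """List of VariantKey with parse diagnostics attached."""

    def __init__(self):
        super().__init__()
        self.n_records = 0
        self.n_skipped = 0


def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            return io.StringIO(data.decode())
        return io.StringIO(data)
    path = Path(source)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    return io.StringIO(raw.decode())


def parse_vcf(source, on_error: str = "skip") -> VcfParseResult:
    """Extract one VariantKey per (record × ALT allele) from a VCF text stream.

    `source` may be a path (plain or gzip) or an open text/binary stream.
    Header lines (starting '#') are skipped.  Multi-allelic records are split
    into one key per ALT.  Malformed records are skipped with a warning
    (`on_error="raise"` propagates instead).
    """
    if on_error not in ("skip", "raise"):
        raise ValueError("on_error must be 'skip' or 'raise'")
    result = VcfParseResult()
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            result.n_records += 1
            fields = line.split("\t")
            if len(fields) < 5:
                fields = line.split()
            try:
                if len(fields) < 5:
                    raise ValueError("fewer than 5 columns")
                chrom, pos_s, _vid, ref, alts = fields[:5]
                pos = int(pos_s)
                for alt in alts.split(","):
                    result.append(VariantKey(chrom, pos, ref, alt))
            except ValueError as exc:
                if on_error == "raise":
                    raise ValueError(f"line {lineno}: {exc}") from exc
                result.n_skipped += 1
                logger.warning("skipping malformed VCF record at line %d: %s", lineno, exc)
    return result


def canonical_serialize(v: VariantKey) -> bytes:
    """Injective pre-hash byte layout: CHROM|POS|REF|ALT ('chr' stripped, upper)."""
    for part in (v.chromosome, v.ref, v.alt):
        if "|" in part:
            raise ValueError("'|' delimiter not allowed inside a field")
    return f"{v.chromosome}|{v.position}|{v.ref}|{v.alt}".encode("ascii")


def hash_variant(v: VariantKey, mac_key: bytes, data_hash_size: int = 48) -> bytes:
    """First `data_hash_size` bits (big-endian prefix) of HMAC-SHA256 of the key."""
    if data_hash_size > 256:
        raise ValueError("data_hash_size cannot exceed 256 (SHA-256 output)")
    if data_hash_size % 8:
        raise ValueError("data_hash_size must be a multiple of 8")
    mac = hmac.new(mac_key, canonical_serialize(v), hashlib.sha256)
    return mac.digest()[: data_hash_size // 8]


def map_index(digest: bytes, x: int) -> int:
    """Integer value of the first x bits of the digest; range [0, 2^x)."""
    if x > 8 * len(digest):
        raise ValueError("x exceeds the number of stored hash bits")
    return int.from_bytes(digest, "big") >> (8 * len(digest) - x)


def hash_and_map(v: VariantKey, mac_key: bytes, data_hash_size: int, x: int) -> HashedVariant:
    digest = hash_variant(v, mac_key, data_hash_size)
    return HashedVariant(digest, map_index(digest, x))


# ---- optional bit-level encoding ----------------------------------------------------

_BASE_BITS = {"A": "00", "C": "01", "G": "10", "T": "11"}
_OPS = {"insertion": "01", "snp": "01", "deletion": "11", "substitution": "10"}
_REF_LEN_BITS = 8  # width of the deletion/substitution ref-length field


def classify_variant(v: VariantKey) -> str:
    if len(v.ref) == 1 and len(v.alt) == 1:
        return "snp"
    if len(v.ref) < len(v.alt) and v.alt.startswith(v.ref):
        return "insertion"
    if len(v.alt) < len(v.ref) and v.ref.startswith(v.alt):
        return "deletion"
    return "substitution"


@dataclass(frozen=True)
class BitEncodedVariant:
    """Compact bit layout: op(2) ‖ chr(5) ‖ pos(28) ‖ type-dependent payload."""

    op: str
    chr_code: str
    pos_code: str
    payload: str
    kind: str

    @property
    def bits(self) -> str:
        return self.op + self.chr_code + self.pos_code + self.payload

    def __len__(self) -> int:
        return len(self.bits)


def encode_bits(v: VariantKey) -> BitEncodedVariant:
    """Bit-encode a variant (a SNP takes 2+5+28+2 = 37 bits)."""
    if v.chromosome not in _CHROM_CODES:
        raise ValueError(f"chromosome {v.chromosome!r} has no 5-bit code")
    if v.position >= 1 << 28:
        raise ValueError("position does not fit in 28 bits")
    kind = classify_variant(v)
    chr_code = format(_CHROM_CODES[v.chromosome], "05b")
    pos_code = format(v.position, "028b")
    if kind in ("snp", "insertion"):
        payload = "".join(_BASE_BITS[b] for b in v.alt)
    elif kind == "deletion":
        payload = format(len(v.ref), f"0{_REF_LEN_BITS}b")
    else:
        payload = format(len(v.ref), f"0{_REF_LEN_BITS}b") + "".join(
            _BASE_BITS[b] for b in v.alt
        )
    return BitEncodedVariant(_OPS[kind], chr_code, pos_code, payload, kind)
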