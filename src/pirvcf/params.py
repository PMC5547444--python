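"""System parameter profiles and key material.

``SystemParams`` bundles everything that fixes the shape of an encoded store
and of the retrieval protocol: hash truncation, bucket mapping width, row
capacity, the FV profile, aggregation and recursion depth.  Named profiles
cover the main operating points: a compact five-million-variant default, a
sparse alternative, a leakage-minimizing variant of the default (subtraction
step enabled), a higher-security profile, and small challenge-style
configurations for pre-counted files.
"""

from __future__ import annotations

import json
import secrets
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import rlwe
from .rlwe import HeKeyPair, RlweParams


@dataclass(frozen=True)
class SystemParams:
    """Full parameter profile governing encoding, padding, and PIR shape."""

    data_hash_size: int = 48  # bits of the keyed hash stored per variant
    bits_for_mapping: int = 13  # x: hash prefix bits used as bucket index
    row_size: int = 716  # slots per bucket (strong-mode capacity)
    fv: RlweParams = field(default_factory=lambda: RlweParams.from_string("FV:80:1024:62:14"))
    aggregation: int = 3  # buckets packed per PIR row
    dimensionality: int = 2  # recursion depth d
    padding_mode: str = "strong"  # "strong" (global capacity) | "weak" (per-file)
    subtraction: bool = False  # run the leakage-minimizing subtraction step

    def __post_init__(self):
        if self.data_hash_size % 8 or not (8 <= self.data_hash_size <= 256):
            raise ValueError("data_hash_size must be a multiple of 8 in [8, 256]")
        if self.bits_for_mapping < 1 or self.bits_for_mapping > self.data_hash_size:
            raise ValueError("bits_for_mapping must be in [1, data_hash_size]")
        if self.row_size < 1:
            raise ValueError("row_size must be ≥ 1")
        if self.aggregation < 1:
            raise ValueError("aggregation must be ≥ 1")
        if not (1 <= self.dimensionality < 4):
            raise ValueError("dimensionality must be 1, 2 or 3")
        if self.padding_mode not in ("strong", "weak"):
            raise ValueError("padding_mode must be 'strong' or 'weak'")

    @property
    def num_entries(self) -> int:
        return 1 << self.bits_for_mapping

    @property
    def slot_bytes(self) -> int:
        return self.data_hash_size // 8

    def with_(self, **kw) -> "SystemParams":
        return replace(self, **kw)

    # ---- (de)serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "data_hash_size": self.data_hash_size,
            "bits_for_mapping": self.bits_for_mapping,
            "num_entries": self.num_entries,
            "row_size": self.row_size,
            "encryption_mode": self.fv.to_string(),
            "aggregation": self.aggregation,
            "dimensionality": self.dimensionality,
            "padding_mode": self.padding_mode,
            "subtraction": self.subtraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemParams":
        d = dict(d)
        d.pop("num_entries", None)
        fv = d.pop("encryption_mode", None)
        if fv is not None:
            d["fv"] = RlweParams.from_string(fv)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SystemParams":
        return cls.from_dict(json.loads(text))


_FV_DEFAULT = "FV:80:1024:62:14"

#: Named profiles mirroring the evaluated configurations.
PROFILES: dict[str, SystemParams] = {
    # compact database tuned for five-million-variant files
    "default": SystemParams(),
    # sparser database: more entries, fewer collisions, heavier aggregation
    "sparse": SystemParams(
        bits_for_mapping=16, row_size=130,
        fv=RlweParams.from_string(_FV_DEFAULT), aggregation=15,
    ),
    # default shape with the subtraction step (no extra variants revealed)
    "no-info": SystemParams(subtraction=True),
    # stronger lattice security (larger ring)
    "security": SystemParams(fv=RlweParams.from_string("FV:172:2048:62:14")),
    # challenge-style profiles (weak per-file padding; small files)
    "idash-1a": SystemParams(
        bits_for_mapping=13, row_size=6, aggregation=4, dimensionality=2,
        padding_mode="weak",
    ),
    "idash-2a": SystemParams(
        bits_for_mapping=17, row_size=6, aggregation=4, dimensionality=3,
        padding_mode="weak",
    ),
    "idash-1b": SystemParams(
        bits_for_mapping=4, row_size=672, aggregation=2, dimensionality=1,
        padding_mode="weak", subtraction=True,
    ),
    "idash-2b": SystemParams(
        bits_for_mapping=9, row_size=256, aggregation=2, dimensionality=2,
        padding_mode="weak", subtraction=True,
    ),
    # small profile exercising every code path quickly (tests, demos)
    "toy": SystemParams(
        bits_for_mapping=6, row_size=40,
        fv=RlweParams.from_string("FV:16:64:40:8"), aggregation=2,
        dimensionality=2,
    ),
}
PROFILES["idash-3a"] = PROFILES["idash-2a"]
PROFILES["idash-3b"] = PROFILES["idash-2b"]


def get_profile(name: str) -> SystemParams:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {', '.join(sorted(PROFILES))}"
        ) from None


@dataclass
class KeyMaterial:
    """The owner's keys: symmetric S, hashing key U, HE pair (R, r)."""

    sym_key: bytes  # S: 256-bit AES key
    mac_key: bytes  # U: HMAC-SHA256 key
    he_keys: HeKeyPair  # (R, r)
    _used_nonces: set = field(default_factory=set, repr=False)

    def __post_init__(self):
        if len(self.sym_key) != 32:
            raise ValueError("S must be 256 bits")
        if len(self.mac_key) < 16:
            raise ValueError("U must be at least 128 bits")
        if self.sym_key == self.mac_key:
            raise ValueError("S and U must be independent keys")

    @classmethod
    def generate(cls, params: SystemParams, seed: int | None = None) -> "KeyMaterial":
        """Fresh keys; deterministic when `seed` is given (tests), OS entropy otherwise."""
        if seed is None:
            sym = secrets.token_bytes(32)
            mac = secrets.token_bytes(32)
            he = rlwe.keygen(params.fv)
        else:
            rng = np.random.default_rng(seed)
            sym = rng.bytes(32)
            mac = rng.bytes(32)
            he = rlwe.keygen(params.fv, seed=rng.integers(0, 2**31))
        return cls(sym_key=sym, mac_key=mac, he_keys=he)

    def fresh_nonce(self, rng=None) -> int:
        """64-bit per-file nonce, guaranteed unused under this S."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        while True:
            nonce = int(rng.integers(0, 2**63, dtype=np.int64))
            if nonce not in self._used_nonces:
                self.register_nonce(nonce)
                return nonce

    def register_nonce(self, nonce: int) -> None:
        if nonce in self._used_nonces:
            raise ValueError(f"nonce {nonce} already used under this symmetric key")
        self._used_nonces.add(nonce)

    # ---- key files ---------------------------------------------------------------
    def save(self, path) -> None:
        blob = {
            "sym_key": self.sym_key.hex(),
            "mac_key": self.mac_key.hex(),
            "he_keys": rlwe.keypair_to_bytes(self.he_keys).hex(),
            "used_nonces": sorted(self._used_nonces),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path) -> "KeyMaterial":
        blob = json.loads(Path(path).read_text())
        km = cls(
            sym_key=bytes.fromhex(blob["sym_key"]),
            mac_key=bytes.fromhex(blob["mac_key"]),
            he_keys=rlwe.keypair_from_bytes(bytes.fromhex(blob["he_keys"])),
        )
        km._used_nonces = set(blob.get("used_nonces", []))
        return km
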