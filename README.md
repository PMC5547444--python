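# pirvcf

Private outsourced storage and oblivious presence queries for genomic
variants.

A clinician or researcher who pushes patients' VCF files to an untrusted
cloud faces two leaks at once: the variants themselves, and the access
pattern of later look-ups ("which variant did the doctor just check?").
`pirvcf` addresses both.  Variant files are reduced to truncated keyed
hashes, placed into a fixed-shape bucketed store, and encrypted at rest;
presence queries then run as computational private information retrieval
(cPIR) over that store, so the server answers *"is chr1:160999478 A→G in
this file?"* without learning the question, the answer, or anything about
the file's contents.

## The scheme

**Encoding (per file).**  A variant is identified by the four VCF
parameters (CHROM, POS, REF, ALT).  Each variant *i* is hashed with
HMAC-SHA256 under a secret key *U*; the first `data_hash_size` bits
*h(i)* are kept (48 by default, so six bytes per variant — a five-million
variant file is ~30 MB of raw payload).  The first *x* bits of *h(i)*
select one of `num_entries = 2^x` buckets; colliding variants are
concatenated within their bucket.  Every bucket is padded to a fixed
`row_size` with PKCS#7-style dummies (the dummy count written in every
dummy byte: three dummies pad as `3‖3‖3`), and each slot is encrypted
under AES-256-CTR with IV = per-file 64-bit nonce ‖ 64-bit global slot
position.  After padding and encryption, every store built from ≤ capacity
variants has the same size and uniformly random content: the server cannot
distinguish a file with one variant from one with five million.

With *x* = 13, five million uniform hashes throw a maximum of ≈ 710
variants into one of the 8192 buckets (balls-into-bins), motivating the
default `row_size = 716`.  The truncated hash trades a false-positive
probability of `n / 2^data_hash_size` (≈ 2⁻²⁵ at five million variants and
48 bits) for compactness — far below DNA sequencing error rates.

**Query (cPIR with absorption).**  The client recomputes *h(j)* for the
variant it seeks, maps it to its bucket, and sends a vector of
homomorphic encryptions — 0 everywhere, 1 at the target row.  The scheme
is a somewhat-homomorphic FV-style cryptosystem over
`R_q = Z_q[x]/(x^n + 1)` supporting *absorption*: `HE(1)·y = HE(y)`,
`HE(0)·y = HE(0)`.  The server multiplies every row by its query entry
and sums — touching every row, so the access pattern reveals nothing —
and returns the single surviving row, which the client decrypts with its
secret keys.  Two knobs shape the traffic:

* **aggregation α** — α buckets are packed into one PIR row: the query
  shrinks to `⌈2^x / α⌉` elements, the reply grows α-fold;
* **dimensionality d** — rows are arranged in a d-dimensional grid and
  the query factors into d near-balanced one-hot vectors (9 rows at d=2
  need 3+3=6 elements instead of 9; the default 2731 rows factor as
  53×52, a 105-element query).  Each extra dimension re-encrypts the
  previous pass's reply, so the reply grows exponentially and d is kept
  below 4.

**Subtraction step (no extra information).**  A plain reply hands the
client the whole aggregated row — its own co-bucket variants.  When the
querier is only *authorized* to learn presence, the client additionally
sends the row-length replication of `E_S(h(j))` (recomputable because CTR
slot ciphertexts depend only on key, nonce and position).  The server
subtracts it from the reply and multiplies each reply ciphertext by a
fresh random odd unit mod `t = 2^D`.  A stored slot matching the
candidate becomes a slot-aligned run of zero coefficients — and zeros are
the only fixed points of unit masking — so the client learns presence
from the zero-run and nothing else.

Parameter profiles are written `FV:A:B:C:D` (security bits, ring degree,
modulus bits, absorbed plaintext bits per coefficient); the default
operating point is `FV:80:1024:62:14`.

## Worked example

```
$ pirvcf init-keys --profile toy --out keys.json --seed 3
wrote keys for FV:16:64:40:8 to keys.json
$ pirvcf synth --n 1000 --seed 5 --out patient1.vcf
wrote 1000 variants to patient1.vcf
$ pirvcf upload --vcf patient1.vcf --keys keys.json --profile toy --out patient1.store
encoded 1000 variants into patient1.store (15360 payload bytes)
$ pirvcf query --store patient1.store --keys keys.json \
    --chrom 1 --pos 2490085 --ref G --alt A --no-extra-info --seed 11
{
  "variant": { "chrom": "1", "pos": 2490085, "ref": "G", "alt": "A" },
  "file_id": "patient1",
  "present": true,
  "mode": "subtract",
  "query_bytes": 8162,
  "reply_bytes": 57722,
  "sub_query_bytes": 4136
}
```

`present: true` — chr1:2490085 G→A is in the store; `mode: "subtract"`
(from `--no-extra-info`) means the verdict came from zero-run detection
and no co-bucket digest was revealed.  The byte counts are the serialized
message sizes a networked deployment would transfer; they are identical
for every target (query a variant that is absent and only `present`
changes).  The 15360-byte payload is exactly `2^6 buckets × 40 slots ×
6 bytes`, independent of how many variants (up to capacity) went in.

`pirvcf plan --variants 5000000` prints the sizing/shape table across the
built-in profiles (store MB, query/reply element counts, modeled transfer
bytes) and `--recommend` picks the profile minimizing modeled transfer
subject to bucket capacity.

## File formats

* **Ciphertext**: magic `PVCT`, version byte, length-prefixed `FV:A:B:C:D`
  string, float64 noise estimate, 8-byte key id, then the two ring
  elements as `degree × ⌈C/8⌉` little-endian coefficient words each.
* **Key file**: JSON with hex `sym_key` (S), `mac_key` (U) and a `PVKP`
  keypair blob (b, a, s serialized like ciphertext parts), plus the
  consumed nonces.
* **Store**: magic `PIRVCF01`, length-prefixed JSON header (parameter
  profile, file id, fixed-width nonce, row size, and — weak padding mode
  only — the variant count), then row-major slot ciphertexts.

## Scope

In-process client/server with wire-ready framing; no TLS/network
transport, no multi-tenant key management, no batched multi-variant
queries, and no concrete lattice security estimation (profiles are taken
as given).
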