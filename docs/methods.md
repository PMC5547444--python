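# Methods

This note records the model behind `pirvcf`, the parameters that matter,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Threat model and protocol

The server is honest-but-curious: it follows the protocol but tries to
infer content or access patterns.  The client owns all keys — a 256-bit
AES key *S* for data at rest, an HMAC-SHA256 key *U* for variant hashing,
and an RLWE keypair (*R*, *r*) for the retrieval layer.  Three properties
are engineered, and each has a direct testable proxy in the suite:

1. **Content confidentiality** — every stored slot is an independent
   AES-256-CTR ciphertext (monobit balance asserted on built stores).
2. **File indistinguishability** — strong padding fixes the store at
   `num_entries · row_size · data_hash_size/8` bytes regardless of the
   variant count; serialized stores of 0, 50 and 400 variants are
   byte-length identical (the header encodes the nonce fixed-width for
   this reason).
3. **Access-pattern hiding** — reply generation touches every row once
   per dimension pass; the instrumented operation counts and the
   serialized query size are asserted constant across targets.

## The somewhat-homomorphic layer

FV-style encryption over `R_q = Z_q[x]/(x^n+1)`, plaintext modulus
`t = 2^D`, Δ = ⌊q/t⌋.  Secret and ephemeral keys are ternary; errors are
centered discrete Gaussians with σ = 3.2 (clipped at 6σ).  Only the
operations the protocol uses exist: encrypt/decrypt, ciphertext addition,
plaintext absorption, plaintext subtraction, and unit-scalar masking.
There is deliberately no relinearization, bootstrapping or batching — the
protocol never multiplies two ciphertexts, and leaving those out removes
both code and noise-budget complexity.

**Modulus choice.**  The profile only fixes the bit length C of q.  For
C ≤ 31, q is the smallest NTT-friendly prime (≡ 1 mod 2n) of exactly C
bits.  For wider moduli q is a *product of two* NTT-friendly primes whose
product has exactly C bits (RNS form): every limb operation then stays
below 2⁶⁴ and vectorizes as plain numpy uint64 arithmetic, with CRT
recombination only at decryption and serialization.  Ciphertexts are kept
in the NTT (evaluation) domain throughout, so absorption and addition are
pointwise; the negacyclic transforms are verified against an O(n²)
schoolbook oracle on small rings.

**Noise accounting.**  Each ciphertext carries a log2 bound on the
standard deviation of its decryption-error term: fresh encryptions start
at `sqrt(2n·σ²·(2/3) + σ²)`; absorption multiplies the bound by
`max(√2, ‖p‖₂)` (the √2 floor keeps the budget strictly decreasing even
for monomial plaintexts); addition combines in quadrature; scalar masking
multiplies by the unit.  The reported budget is
`log2(Δ/2) − 1 − log2(6) − log2(noise std)` bits — a 6σ tailcut plus one
bit of slack for the Δ-rounding residue.  This is an estimate, not a
measurement of the secret noise; its calibration is validated by a
Monte-Carlo test (200 random operation chains whose predicted budget
stays positive must decrypt exactly) and decryption warns when the budget
is exhausted.

## Packing and the subtraction width D′

Row payloads are packed *slot-aligned*: each `data_hash_size`-bit slot is
split big-endian into `⌈slot_bits/w⌉` base-2^w digits, so a slot occupies
whole coefficients and the zero-run test cannot straddle slots.
Recursion payloads (serialized ciphertexts of the previous pass) are
packed as a plain bit stream at the full width D.

In subtraction mode the reply absorbs one extra multiplication by a mask
of size up to t, which costs up to D noise bits.  The data width is
therefore reduced to the largest D′ ≤ D for which the noise model above
still leaves ≥ 1 bit of budget after absorb + first-dimension row
summation + mask.  Computing D′ from the same model that tracks runtime
noise keeps the two consistent by construction; at the default profile
and d = 2 this yields D′ = 13 of D = 14.

**Masking granularity.**  Ideally every coefficient of the reply would
get an independent multiplier.  A single plaintext multiplication can
only apply one ring element; a non-constant mask polynomial would mix
coefficients and destroy the zero-run alignment, so the implementation
draws one independent random odd unit per reply *ciphertext*.  Residual
structure — ratios between coefficients within one masked ciphertext are
preserved — is a known, documented leakage of this granularity; zero
coefficients are still exactly the fixed points, so the presence verdict
itself leaks nothing extra.

## Recursion composition

For d > 1 the `⌈2^x/α⌉` aggregated rows are padded with zero rows to an
`n_1 × … × n_d` grid (near-balanced factors, `n_1 = ⌈rows^(1/d)⌉` then
greedy; 9 → 3×3, 2731 → 53×52).  Pass 1 computes, for each of the
`n_2·…·n_d` residual coordinates, the absorption dot-product along
dimension 1.  When the subtraction step is active it applies here — to
*every* pass-1 reply, since the server must not know which one matters.
Each pass then serializes its replies and packs them as the database of
the next pass.  The client unwinds in reverse, deserializing and
decrypting layer by layer.  The per-pass expansion factor (serialized
ciphertext bytes / absorbed payload bytes) is what makes the reply grow
exponentially in d, hence the d < 4 bound.

## At-rest encryption

One full AES-256 counter block is spent per slot even though slots are 6
(or 12) bytes: IV = file nonce (64 bits) ‖ global slot position
(`bucket·row_size + slot`, 64 bits).  This wastes ≤ 10 keystream bytes
per slot (costing nothing in storage) and buys two properties the
subtraction step requires: counter uniqueness without bookkeeping, and
client-side recomputability of any single slot's ciphertext.  The
"position" in the IV is the slot coordinate, not a running variant
counter — only the former is recomputable by a client that does not know
the server-side insertion history.  Nonce reuse under one key is refused
at build time; the key file records consumed nonces.

Duplicate digests within a bucket are stored once (presence queries have
set semantics).  Dummy slot values are taken mod 256 and repeated across
the slot's bytes, which keeps the padding well-defined when dummy counts
exceed one byte; unpadding disambiguates counts above 255 by matching the
longest consistent suffix.

## Parameter choices

| Parameter | Default | Why |
|---|---|---|
| `data_hash_size` | 48 bits | 6 bytes/variant; false-positive probability 5·10⁶/2⁴⁸ ≈ 2⁻²⁵, below sequencing error rates. 96 bits supported for cryptographically negligible error. |
| `bits_for_mapping` (x) | 13 | 8192 buckets; mean max load ≈ 710 at five million variants keeps the padded store ~35 MB. |
| `row_size` | 716 | Covers the expected maximum collision count at capacity with small margin. |
| FV profile | `FV:80:1024:62:14` | 80-bit-security operating point; `FV:172:2048:62:14` for >128-bit security. |
| `aggregation` | 3 | 2731 PIR rows; balances query length against reply size. |
| `dimensionality` | 2 (53×52) | 105-element query; d=3 replies are disproportionately large at this shape. |
| σ (noise) | 3.2, 6σ tailcut | Common discrete-Gaussian operating point for FV-family schemes. |
| padding | strong | Weak (per-file) mode supported where hiding the variant count is waived; the leak is recorded in the store header. |

The planner's recommender scores candidate profiles by a closed-form
communication model (serialized query + reply + sub-query bytes) subject
to `row_size ≥ expected max load`, with deterministic tie-breaks (smaller
reply, then candidate order).  It deliberately does not model wall-clock
time, which is hardware-bound.

## Bit-level variant encoding

The optional compact encoding is op(2) ‖ chr(5) ‖ pos(28) ‖ payload:
insertion/SNP = `01` with 2 bits per alternate base (a SNP is 37 bits),
deletion = `11` with an 8-bit reference-length field, substitution = `10`
with length ‖ alternate.  Two open points are resolved here as package
choices: substitution gets a distinct op code (a 2-bit code space has
room for four types), and the deletion length field is fixed at 8 bits.
Base codes are alphabetical (A=00, C=01, G=10, T=11); chromosomes 1–22
map to 1–22, X=23, Y=24, MT=25.

## Synthetic data

The generator emits deterministic VCF text (header + 8-column body) with
unique (CHROM, POS, REF, ALT) tuples, positions uniform within
per-chromosome bounds, and a 9:1 SNP:indel mix.  Positions are uniform
rather than empirically distributed on purpose: every statistic the
protocol depends on flows through the keyed hash, which uniformizes any
input, so positional realism is irrelevant to correctness.  What passing
tests therefore show is correctness and shape-invariance of the pipeline
— not robustness to VCF dialect quirks (symbolic alleles, structural
variants, genotype columns) which the parser skips by design, nor
population-genetic realism (allele frequencies, linkage).

Protocol tests run on 500–1000-variant stores with a small 64-bucket
shape, under both the toy ring (`FV:16:64:40:8`) and the full default
ring; the acceptance-scale collision statistic runs the genuine
five-million-throw simulation.  These sizes were chosen so the full suite
exercises every configuration (two rings × d ∈ {1,2,3} × both modes)
while remaining a ~1-minute run.

## Degenerate inputs and edge behavior

Empty VCF → a store of pure padding (still full-size in strong mode);
empty rows pad to `row_size` dummies of value `row_size mod 256`;
`num_entries` not divisible by aggregation → the trailing aggregated row
is zero-filled, and grid padding adds zero rows the query can never
select; malformed VCF records are skipped with a logged warning and
counted; a query for a variant absent from the store returns a verdict
whose false-positive probability is the union bound above.

## Known limitations

Per-ciphertext (not per-coefficient) masking granularity, as discussed;
O(files · rows) server work per multi-file search; pure-Python/numpy
throughput is orders of magnitude below an optimized native lattice
library, so absolute timings are not meaningful and are nowhere asserted;
no verifiable-computation audit of the server; truncated-hash false
positives are inherent to the encoding (the bit-level encoding removes
them at the cost of a larger store).
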