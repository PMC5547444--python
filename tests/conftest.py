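import numpy as np
import pytest

from pirvcf.client import PirClient, StoreHandle
from pirvcf.params import KeyMaterial, SystemParams, get_profile
from pirvcf.rlwe import RlweParams
from pirvcf.server import PirServer
from pirvcf.store import build_store
from pirvcf.synth import generate_keys


@pytest.fixture(scope="session")
def tiny_fv():
    """Toy ring small enough for exhaustive/schoolbook oracles."""
    return RlweParams(security_bits=8, degree=16, coeff_bits=20, absorb_bits=4)


@pytest.fixture(scope="session")
def default_fv():
    return RlweParams.from_string("FV:80:1024:62:14")


@pytest.fixture(scope="session")
def toy_system():
    return get_profile("toy")


@pytest.fixture(scope="session")
def toy_keys(toy_system):
    return KeyMaterial.generate(toy_system, seed=101)


@pytest.fixture(scope="session")
def small_variants():
    """500 unique synthetic variants, deterministic."""
    return generate_keys(500, seed=42)


@pytest.fixture(scope="session")
def toy_store(toy_system, toy_keys, small_variants):
    return build_store(
        small_variants, toy_keys, toy_system, file_id="toy", nonce=12345
    )


@pytest.fixture()
def protocol_rig(toy_system, toy_keys, toy_store):
    """(client, server, handle) wired to the session toy store."""
    server = PirServer(rng=7)
    server.add_store(toy_store)
    client = PirClient(toy_keys, toy_system, rng=13)
    return client, server, StoreHandle.of(toy_store)


@pytest.fixture(scope="session")
def absent_variants(small_variants):
    """Variants guaranteed not to be in the small store."""
    present = {(v.chromosome, v.position, v.ref, v.alt) for v in small_variants}
    extra = [v for v in generate_keys(80, seed=4242)
             if (v.chromosome, v.position, v.ref, v.alt) not in present]
    assert len(extra) >= 50
    return extra[:50]
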