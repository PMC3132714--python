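import pytest

from blobcache.fixtures import FixtureSpec, MockUpstream, generate_fixture
from blobcache.store import BlobStore


@pytest.fixture
def fixture_dir(tmp_path):
    """A small deterministic fixture file tree plus its ground truth."""
    out = tmp_path / "fixture"
    manifest = generate_fixture(FixtureSpec(seed=42), out)
    return out, manifest


@pytest.fixture
def upstream(fixture_dir):
    """Instrumented mock upstream serving the fixture files."""
    out, manifest = fixture_dir
    server = MockUpstream()
    server.serve_directory(out)
    server.start()
    yield server
    server.stop()


@pytest.fixture
def store(tmp_path):
    return BlobStore(tmp_path / "store")


def commit_fixture_blob(store, fixture_dir, metadata=None):
    """Copy the fixture files into a committed blob; gene table is
    decompressed to the name the services expect."""
    import gzip

    staging = store.begin_build()
    for name in ("ontology.obo", "annotations.tsv", "mesh.tsv",
                 "interactions.tsv", "orthologs.tsv"):
        staging.write_bytes(name, (fixture_dir / name).read_bytes())
    staging.write_bytes(
        "genes.tsv", gzip.decompress((fixture_dir / "genes.tsv.gz").read_bytes())
    )
    return store.commit(staging, metadata=metadata or {"origin": "fixture"})
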