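import pytest

import wrkykit as w


@pytest.fixture(scope="session")
def default_proteome():
    """Seeded default synthetic proteome (mutation rate 0) with its truth table."""
    spec = w.SynthSpec(seed=1)
    return w.generate_proteome(spec)


@pytest.fixture(scope="session")
def reference_set():
    return w.load_reference_set()


@pytest.fixture()
def fasta_file(tmp_path):
    def write(records, name="seqs.faa"):
        path = tmp_path / name
        w.write_fasta(records, path)
        return path

    return write
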