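import pytest

from primermap import DesignParameters, GeneratorSpec, generate_records
from primermap.seq_io import SequenceRecord


@pytest.fixture
def default_params():
    return DesignParameters()


@pytest.fixture
def small_params():
    """Parameters sized for fast exhaustive comparisons."""
    return DesignParameters(
        five_prime_window=80, three_prime_window=80,
        len_min=18, len_max=22,
        gc_min=35.0, gc_max=65.0, tm_min=48.0, tm_max=68.0,
    )


@pytest.fixture
def seeded_records():
    records, _ = generate_records(
        GeneratorSpec(n_records=5, length_range=(300, 500), seed=42)
    )
    return records


@pytest.fixture
def single_record():
    records, _ = generate_records(
        GeneratorSpec(n_records=1, length_range=(400, 400), seed=7)
    )
    return records[0]


@pytest.fixture
def fasta_file(tmp_path, seeded_records):
    from primermap.seq_io import write_fasta
    path = tmp_path / "input.fasta"
    write_fasta(seeded_records, path)
    return path


def make_record(seq, rec_id="t1"):
    return SequenceRecord(id=rec_id, seq=seq)
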