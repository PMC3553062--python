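import pytest

from mircms.io import SequenceRecord


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write (name, sequence) pairs to a temp FASTA and return its path."""

    def _write(records, name="input.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for ident, seq in records:
                fh.write(f">{ident}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_fastq_file(tmp_path):
    def _write(records, name="input.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for ident, seq, qual in records:
                fh.write(f"@{ident}\n{seq}\n+\n{qual}\n")
        return path

    return _write


def make_records(*seqs):
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs, start=1)]
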