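import random

import pytest

from isomirsea import AlignmentParams, MatureRecord, build_seed_index

#: 22-nt reference used across tests; seed (nt 2-7) is AGCTTA.
REF_SEQ = "TAGCTTATCAGACTGATGTTGA"


@pytest.fixture
def params():
    return AlignmentParams()


@pytest.fixture
def mature():
    return MatureRecord(id="hsa-miR-x", species_code="hsa", sequence=REF_SEQ)


@pytest.fixture
def single_index(mature, params):
    return build_seed_index([mature], params)


@pytest.fixture
def make_index(params):
    def _make(*records):
        return build_seed_index(list(records), params)

    return _make


def substitute(seq: str, pos: int, rng: random.Random | None = None) -> str:
    """Replace the base at 1-based ``pos`` with a different one."""
    rng = rng or random.Random(0)
    old = seq[pos - 1]
    new = rng.choice([b for b in "ACGT" if b != old])
    return seq[: pos - 1] + new + seq[pos:]


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")
    return path
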