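import pytest

from msapkit.msap import BandCall, MethylationState

STATES = list(MethylationState)


@pytest.fixture
def ttt_column() -> list[BandCall]:
    """A 926-locus column with the bundled TTT state counts: 489/140/292/5."""
    counts = {
        MethylationState.UNMETHYLATED: 489,
        MethylationState.CHG: 140,
        MethylationState.CG: 292,
        MethylationState.CG_CHG: 5,
    }
    column = []
    for state, n in counts.items():
        column.extend([state.band_call] * n)
    return column


@pytest.fixture
def band_matrix_file(tmp_path):
    """A 3-locus, 2-sample band matrix TSV with one NA cell."""
    path = tmp_path / "bands.tsv"
    path.write_text(
        "locus_id\tREF_H\tREF_M\tS1_H\tS1_M\n"
        "L1\t1\t1\t1\t1\n"
        "L2\t0\t1\t1\t1\n"
        "L3\t1\t0\tNA\t0\n"
    )
    return path
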