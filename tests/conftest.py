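import pytest

from menzerath.ss_io import ProteinRecord, SegmentKind, SSegment


def protein(accession: str, lengths, locations=(), seq_length=None) -> ProteinRecord:
    """Build a ProteinRecord from segment lengths (helix/strand alternating)."""
    kinds = [SegmentKind.HELIX, SegmentKind.STRAND]
    segments = tuple(SSegment(kinds[i % 2], int(L)) for i, L in enumerate(lengths))
    total = sum(lengths)
    return ProteinRecord(
        accession=accession,
        seq_length=seq_length if seq_length is not None else int(total) + 10,
        segments=segments,
        locations=frozenset(locations),
    )


@pytest.fixture
def fig1_protein():
    """The worked per-protein example: three segments of 29, 15 and 20 AA."""
    return protein("P1", (29, 15, 20), locations={"Cell membrane"})
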