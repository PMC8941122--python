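import pytest

from crkscan.domain_architecture import Architecture
from crkscan.io_formats import DomainHit


def make_arch(labels, protein_id="P1", domain_len=100, gap=40):
    """Architecture with the given label sequence at evenly spaced coordinates."""
    elements = []
    cursor = 1
    for label in labels:
        elements.append((label, cursor, cursor + domain_len - 1))
        cursor += domain_len + gap
    return Architecture(protein_id=protein_id, elements=tuple(elements))


def make_hits(spans, protein_id="P1", name="Stress-antifungal"):
    """DomainHit list from (start, end, bit_score[, name]) tuples."""
    hits = []
    for span in spans:
        if len(span) == 4:
            start, end, score, label = span
        else:
            start, end, score = span
            label = name
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_name=label,
                start=start,
                end=end,
                e_value=1e-10,
                bit_score=float(score),
                significant=True,
            )
        )
    return hits


@pytest.fixture
def arch_factory():
    return make_arch


@pytest.fixture
def hit_factory():
    return make_hits
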