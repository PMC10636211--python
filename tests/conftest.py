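import pytest
from hypothesis import HealthCheck, settings

from evescan.search import ScoringScheme, TranslatedHit

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


def make_hit(
    contig="c1", frame=1, sstart=0, send=300, score=200, evalue=1e-20,
    query="q1", qstart=0, qend=100, identity=90.0,
) -> TranslatedHit:
    """Minimal hit for catalogue-level tests (aligned strings unused there)."""
    return TranslatedHit(
        query_id=query, contig_id=contig, frame=frame,
        subject_start=sstart, subject_end=send,
        query_start=qstart, query_end=qend,
        raw_score=score, bit_score=float(score), evalue=evalue,
        percent_identity=identity, aligned_query="", aligned_subject="",
    )


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))
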