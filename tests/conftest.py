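import numpy as np
import pytest

from m6amseq import (
    LibraryRole,
    PositionTracks,
    SimParams,
    compute_tracks,
    generate_transcriptome,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A small but fully featured simulation: 60 transcripts, a quarter
    with cap m6Am and a quarter with internal m6A, 60k fragments/library."""
    return SimParams(n_transcripts=60, depth_per_library=60_000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_params):
    transcripts, truth = generate_transcriptome(small_params)
    alignments = simulate_libraries(transcripts, truth, small_params)
    return transcripts, truth, alignments


@pytest.fixture(scope="session")
def small_tracks(small_sim):
    transcripts, _, alignments = small_sim
    return compute_tracks(alignments, transcripts)


def make_tracks(
    length: int = 200,
    depth: dict[LibraryRole, np.ndarray] | None = None,
    start_count: dict[LibraryRole, np.ndarray] | None = None,
    library_size: int | None = None,
    tid: str = "tx",
) -> dict[str, PositionTracks]:
    """Hand-built single-transcript tracks for direct-construction tests.

    When ``library_size`` is omitted it is set to 1e6 so that cpm values
    equal raw depth values.
    """
    tr = PositionTracks(tid, length)
    depth = depth or {}
    start_count = start_count or {}
    roles = set(depth) | set(start_count)
    for role in roles:
        d = depth.get(role, np.zeros(length, dtype=np.int64))
        s = start_count.get(role, np.zeros(length, dtype=np.int64))
        tr.depth[role] = np.asarray(d, dtype=np.int64)
        tr.start_count[role] = np.asarray(s, dtype=np.int64)
        tr.library_size[role] = library_size or 1_000_000
    return {tid: tr}
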