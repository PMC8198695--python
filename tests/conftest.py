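import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cfocr.io_fragments import Fragment, GenomeTile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fragments(
    rng: np.random.Generator,
    tile: GenomeTile,
    n: int,
    length_range: tuple[int, int] = (120, 180),
) -> list[Fragment]:
    """Random mononucleosome-sized fragments overlapping the tile."""
    lo = max(0, tile.padded_start - length_range[1])
    starts = rng.integers(lo, tile.padded_end, n)
    lengths = rng.integers(length_range[0], length_range[1] + 1, n)
    return [Fragment(tile.contig, int(s), int(s + l)) for s, l in zip(starts, lengths)]


@pytest.fixture
def small_tile():
    return GenomeTile("chrT", 1000, 6000, pad=0, contig_length=200_000)
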