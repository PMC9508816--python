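import numpy as np
import pytest
from hypothesis import settings

from ppredit import ConsensusProfile, TargetWindow, build_profile, make_factor

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ppr56_like():
    return make_factor("PPR56-like")


def window_from(bases: dict[int, str], lo: int = -30, hi: int = 5,
                fill: str = "A", gene: str = "g", transcript: str = "t",
                position: int = 100, rate=None) -> TargetWindow:
    """Window helper: explicit bases at given offsets, ``fill`` elsewhere,
    C forced at offset 0 unless overridden."""
    chars = {o: fill for o in range(lo, hi + 1)}
    chars[0] = "C"
    chars.update(bases)
    seq = "".join(chars[o] for o in range(lo, hi + 1))
    return TargetWindow(gene, transcript, position, seq, lo=lo, edit_rate=rate)


def balanced_windows(n: int, overrides: dict[int, list[str]],
                     lo: int = -30, hi: int = 5) -> list[TargetWindow]:
    """n windows whose base composition is exactly 25% per nucleotide at
    every offset except those in ``overrides`` (a per-window base list) and
    offset 0 (always C).  Requires n divisible by 4."""
    assert n % 4 == 0
    cycle = "ACGT"
    out = []
    for i in range(n):
        bases = {o: cycle[(i + o) % 4] for o in range(lo, hi + 1)}
        bases[0] = "C"
        for o, col in overrides.items():
            bases[o] = col[i]
        seq = "".join(bases[o] for o in range(lo, hi + 1))
        out.append(TargetWindow(f"g{i}", f"t{i}", 100, seq, lo=lo))
    return out


def column(n: int, dominant: str, count: int) -> list[str]:
    """A base column of length n: ``count`` copies of ``dominant``, the rest
    split as evenly as possible over the other three nucleotides."""
    others = [b for b in "ACGT" if b != dominant]
    rest = n - count
    col = [dominant] * count
    for i in range(rest):
        col.append(others[i % 3])
    return col


@pytest.fixture()
def profile_a40_at_m14() -> ConsensusProfile:
    """Profile over offsets -17..-1 whose single thresholded position is
    -14 with A at frequency 0.43."""
    windows = balanced_windows(100, {-14: column(100, "A", 43)})
    return build_profile(windows, bounds=(-17, -1))


@pytest.fixture()
def profile_g70_at_m13() -> ConsensusProfile:
    """Profile over offsets -17..-1 whose single thresholded position is
    -13 with G at frequency 0.74."""
    windows = balanced_windows(100, {-13: column(100, "G", 74)})
    return build_profile(windows, bounds=(-17, -1))
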