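import numpy as np
import pytest

from g4reps import GenomeRecord, builtin_presets
from g4reps.synthetic_data import SurveyParams, simulate_survey


@pytest.fixture(scope="session")
def xan():
    return builtin_presets()["xan"]


@pytest.fixture(scope="session")
def ana():
    return builtin_presets()["ana"]


@pytest.fixture(scope="session")
def clean_survey(xan):
    """A noiseless synthetic survey: planted truth is exactly recoverable."""
    params = SurveyParams(
        seed=11, degenerate_position_mut_rate=0.0, g_tract_mut_rate=0.0
    )
    return simulate_survey(params, xan)


@pytest.fixture(scope="session")
def noisy_survey(xan):
    """Survey at the default mutation rates."""
    return simulate_survey(SurveyParams(seed=12), xan)


def motif_rich_sequence(rng: np.random.Generator, length: int, preset) -> str:
    """Random background salted with seed/degenerate/partial fragments,
    adversarial for array-boundary and overlap handling."""
    from g4reps.genome_io import revcomp

    seeds = sorted(preset.seed_units)
    pat = preset.degenerate_unit

    def random_unit() -> str:
        return "".join(
            b if b != "N" else "ACGT"[rng.integers(0, 4)] for b in pat
        )

    pieces = []
    n = 0
    while n < length:
        r = rng.random()
        if r < 0.45:
            k = int(rng.integers(5, 40))
            frag = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        elif r < 0.65:
            frag = seeds[rng.integers(0, len(seeds))]
        elif r < 0.80:
            frag = random_unit()
        elif r < 0.88:
            frag = "G" * int(rng.integers(1, 5))
        else:
            frag = revcomp(seeds[rng.integers(0, len(seeds))])
        pieces.append(frag)
        n += len(frag)
    return "".join(pieces)[:length]


@pytest.fixture()
def rng():
    return np.random.default_rng(20150144)


def make_genome(seq: str, gid: str = "test") -> GenomeRecord:
    return GenomeRecord(id=gid, sequence=seq)
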