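"""Shared setup for the numbered analysis scripts.

Every script regenerates its inputs deterministically from SEED through the
synthetic cohort generator, so the scripts can run in any order; outputs land
under results/.
"""

from pathlib import Path

from claudinlow.synthetic import SyntheticConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def train_config() -> SyntheticConfig:
    return SyntheticConfig(seed=SEED)


def test_config() -> SyntheticConfig:
    return SyntheticConfig(seed=SEED + 1000)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
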