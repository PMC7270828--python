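from __future__ import annotations

import numpy as np
import pytest

from epipair import default_barcode_table

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_fragments(rng: np.random.Generator, lengths) -> dict[str, str]:
    return {f"f{i:04d}": random_dna(rng, int(L)) for i, L in enumerate(lengths)}


def expected_reconstruction(fragment: str, half: int = 86, pad_removed: bool = True,
                            min_overlap: int = 10) -> str:
    """Independent oracle for what an ideal pipeline can recover from a
    fragment given fixed-length read halves: the full fragment when the
    two halves overlap detectably (or abut exactly), otherwise the two
    halves concatenated."""
    L = len(fragment)
    overlap = 2 * half - L
    if overlap == 0 or overlap >= min_overlap:
        return fragment if overlap >= 0 else fragment[:half] + fragment[-half:]
    if overlap < 0:
        return fragment[:half] + fragment[-half:]
    raise ValueError(
        f"fragment length {L} gives an undetectable overlap of {overlap}"
    )


@pytest.fixture(scope="session")
def barcodes() -> dict[str, str]:
    return default_barcode_table()


@pytest.fixture(scope="session")
def four_barcodes(barcodes) -> dict[str, str]:
    # four samples with distinct barcode lengths (5, 6, 8, 9)
    keep = ["AlDA1", "AlDA2", "AlDB2", "AlPB1"]
    return {k: barcodes[k] for k in keep}
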