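import random

import pytest

from congruphy.characters import INAPPLICABLE, MISSING, MORPHOLOGY, CharacterMatrix


def toy_matrix(taxa, columns, tag=MORPHOLOGY):
    """Build a matrix from per-column state strings, e.g. ['0011', '01?-'].

    '?' = missing, '-' = inapplicable, anything else a single state symbol.
    """
    cells = []
    for i in range(len(taxa)):
        row = []
        for col in columns:
            ch = col[i]
            if ch == "?":
                row.append(MISSING)
            elif ch == "-":
                row.append(INAPPLICABLE)
            else:
                row.append(frozenset(ch))
        cells.append(row)
    return CharacterMatrix(list(taxa), cells, [tag] * len(columns))


@pytest.fixture
def rng():
    return random.Random(20240917)
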