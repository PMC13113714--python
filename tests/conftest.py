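import pytest

from paleophony.characters import CharacterMatrix


def make_matrix(taxa, rows, **kwargs):
    """Matrix from per-taxon state strings; '?'/'-' missing, '{..}' polymorphic."""
    cells = []
    for row in rows:
        out = []
        i = 0
        while i < len(row):
            ch = row[i]
            if ch in "?-":
                out.append(None)
                i += 1
            elif ch == "{":
                j = row.index("}", i)
                out.append(frozenset(row[i + 1:j]))
                i = j + 1
            else:
                out.append(frozenset({ch}))
                i += 1
        cells.append(tuple(out))
    return CharacterMatrix(taxa=tuple(taxa), cells=tuple(cells), **kwargs)


@pytest.fixture
def quartet_matrix():
    return make_matrix("ABCD", ["0", "0", "1", "1"])


@pytest.fixture
def default_cohort():
    from paleophony.synthetic import CohortConfig, simulate_cohort
    return simulate_cohort(CohortConfig(seed=1))
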