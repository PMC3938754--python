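import pytest

from proteocost import CellModel, FixationParams, ProteinSpec


@pytest.fixture
def cell():
    """Default yeast cell (physical RT at 37 C)."""
    return CellModel()


@pytest.fixture
def parity_cell():
    """Cell with RT pinned to 2.5 kJ/mol, matching the worked yeast numbers."""
    return CellModel(rt_override=2.5)


@pytest.fixture
def protein():
    """Average yeast protein: 467 aa, 1e4 copies, dG=-37 kJ/mol, 43-min
    half-life, default handling costs."""
    return ProteinSpec()


@pytest.fixture
def yeast_pop():
    return FixationParams(n_eff=1.0e7)
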