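import warnings

import numpy as np
import pytest

from drugclf import (
    DesignMatrix,
    LabeledCellSet,
    PanelSimConfig,
    SingleCellSimConfig,
    generate_cell_line_panel,
    generate_single_cell_dataset,
)

# sklearn's coordinate-descent warnings at tight tolerances are expected noise
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def small_cellset() -> LabeledCellSet:
    """40+40 cells, 20 genes, clear but imperfect signal."""
    data, _ = generate_single_cell_dataset(
        SingleCellSimConfig(
            n_healthy=40, n_tumor=40, n_genes=20, n_informative=5,
            effect_size=1.5, seed=101,
        )
    )
    return data


@pytest.fixture(scope="session")
def nosignal_cellset() -> LabeledCellSet:
    data, _ = generate_single_cell_dataset(
        SingleCellSimConfig(
            n_healthy=30, n_tumor=30, n_genes=15, n_informative=0,
            effect_size=0.0, seed=202,
        )
    )
    return data


@pytest.fixture(scope="session")
def small_panel():
    """Desk-scale cell-line panel: 45 lines, 120 genes, 6 drugs, one null drug."""
    return generate_cell_line_panel(
        PanelSimConfig(n_lines=45, n_genes=120, n_drugs=6, n_null_drugs=1, seed=303)
    )


@pytest.fixture(scope="session")
def comp_panel():
    """Panel with a planted complementary drug pair (drugs 0 and 1)."""
    return generate_cell_line_panel(
        PanelSimConfig(
            n_lines=45, n_genes=120, n_drugs=8, complementary_pair=(0, 1), seed=404
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def toy_design(n=6, p=2, seed=0):
    r = np.random.default_rng(seed)
    return DesignMatrix(
        r.normal(size=(n, p)),
        [f"f{j}" for j in range(p)],
        [f"s{i}" for i in range(n)],
    )
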