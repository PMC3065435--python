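import numpy as np
import pytest

from mirmod import ExpressionMatrix, MapMatrix


@pytest.fixture
def tiny_map() -> MapMatrix:
    """4 mRNAs x 3 miRNAs with two co-targeting pairs of rows."""
    values = np.array(
        [
            [1, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
            [0, 1, 1],
        ]
    )
    return MapMatrix(["g1", "g2", "g3", "g4"], ["m1", "m2", "m3"], values)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    values = np.array(
        [
            [0.0, 0.1],
            [0.1, 0.0],
            [5.0, 5.2],
            [5.1, 4.9],
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3", "g4"], ["t1", "t2"], values)


@pytest.fixture
def block_map() -> MapMatrix:
    """Two clean co-targeting blocks of 4 mRNAs each, tagged by dedicated miRNAs."""
    values = np.zeros((8, 4), dtype=int)
    values[:4, :2] = 1
    values[4:, 2:] = 1
    return MapMatrix(
        [f"g{j}" for j in range(1, 9)], [f"m{i}" for i in range(1, 5)], values
    )


@pytest.fixture
def block_expr() -> ExpressionMatrix:
    """Expression separating the two blocks of block_map."""
    rng = np.random.default_rng(7)
    values = np.vstack(
        [
            np.array([0.0, 0.0, 0.0]) + 0.01 * rng.standard_normal((4, 3)),
            np.array([4.0, -4.0, 4.0]) + 0.01 * rng.standard_normal((4, 3)),
        ]
    )
    return ExpressionMatrix([f"g{j}" for j in range(1, 9)], ["t1", "t2", "t3"], values)
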