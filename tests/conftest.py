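import numpy as np
import pytest

from spatvax import (
    SimulationSpec,
    build_queen_weights,
    build_rook_weights,
    generate_grid_layer,
    row_standardize,
    simulate_field,
)


def grid_weights(nrows, ncols, kind="queen", standardize=True):
    layer = generate_grid_layer(nrows, ncols)
    build = build_queen_weights if kind == "queen" else build_rook_weights
    w = build(layer)
    return row_standardize(w) if standardize else w


@pytest.fixture(scope="session")
def queen4():
    return grid_weights(4, 4)


@pytest.fixture(scope="session")
def rook4():
    return grid_weights(4, 4, kind="rook")


@pytest.fixture(scope="session")
def queen5():
    return grid_weights(5, 5)


@pytest.fixture(scope="session")
def queen8():
    return grid_weights(8, 8)


@pytest.fixture(scope="session")
def queen20():
    """20x20 queen lattice shared by the model-recovery tests (eigenvalues
    are cached on the object, so sharing saves repeated spectra)."""
    return grid_weights(20, 20)


def sar_dataset(w, kind, param, seed, beta=(1.0, 2.0), sigma=1.0):
    """One draw of the lag/error generating process on a square lattice:
    two percentage predictors around 50 and 40 (sd 3), outcome centred at
    62 so the [0, 100] clipping stays inactive."""
    side = int(np.sqrt(w.n))
    spec = SimulationSpec(
        nrows=side,
        ncols=side,
        process=kind,
        rho_or_lambda=param,
        beta=list(beta),
        sigma=sigma,
        predictor_means=[50.0, 40.0],
        predictor_sds=[3.0, 3.0],
        outcome_means={"y": 62.0},
        seed=seed,
    )
    ds = simulate_field(spec, w)
    y = ds.attributes["y"].to_numpy()
    X = ds.attributes[["x1", "x2"]].to_numpy()
    return y, X


# ---- independent oracles -------------------------------------------------

def moran_brute(x, Wdense):
    """Double-loop evaluation of global Moran's I."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += Wdense[i, j] * z[i] * z[j]
    return n / Wdense.sum() * num / (z @ z)


def moran_bv_brute(x, y, Wdense):
    """Double-loop bivariate Moran's I on z-standardized variables
    (denominator in y), mirroring the GeoDa convention."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += Wdense[i, j] * zx[i] * zy[j]
    return n / Wdense.sum() * num / (zy @ zy)


def lisa_brute(x, Wdense):
    """Per-unit local Moran by explicit loops."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    denom = z @ z
    out = np.empty(n)
    for i in range(n):
        lag = sum(Wdense[i, j] * z[j] for j in range(n))
        out[i] = n * z[i] * lag / denom
    return out
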