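import warnings

import numpy as np
import pytest

from cardionuc import mechanics as M
from cardionuc import synthetic as S
from cardionuc import traces as T


@pytest.fixture(scope="session")
def wt_model():
    return M.build_model()


@pytest.fixture(scope="session")
def wt_solution(wt_model):
    return M.solve_prestress(wt_model)


@pytest.fixture(scope="session")
def refined_solution():
    return M.solve_prestress(M.build_model(mesh_density=1))


@pytest.fixture(scope="session")
def condition_table():
    return M.compare_conditions()


@pytest.fixture(scope="session")
def condition_solutions():
    return {name: M.solve_condition(name)
            for name in ("WT", "LMNA", "LINC", "LMNA_LINC")}


@pytest.fixture(scope="session")
def wt_trace_metrics():
    """Coupling metrics for 20 synthetic WT cells (fixed seed)."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for cell in S.gen_traces(seed=1, preset="WT"):
            series = T.pair_series(cell["sarcomere_length"],
                                   cell["nuclear_length"],
                                   cell["nuclear_width"])
            out.append((T.coupling_metrics(series), cell["truth"]))
    return out


def make_series(t, eps_s, eps_n, eps_w=None):
    """Small helper: wrap arrays into a PairedStrainSeries."""
    eps_w = np.zeros_like(eps_s) if eps_w is None else eps_w
    return T.PairedStrainSeries(t=np.asarray(t, float),
                                eps_s=np.asarray(eps_s, float),
                                eps_nL=np.asarray(eps_n, float),
                                eps_nW=np.asarray(eps_w, float),
                                L0_s=1.85, L0_nL=12.0, L0_nW=6.0)
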