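import numpy as np
import pytest

from amdml import MultiViewDataset, ViewGraphs
from amdml.graphs import build_pair_sets


def random_labeled_dataset(rng, n=20, D=6, M=2, separation=1.0):
    """Random labeled multi-view data with mild class structure."""
    n_pos = n // 2
    labels = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n - n_pos, dtype=int)])
    views = []
    for m in range(M):
        u = rng.normal(size=D)
        u /= np.linalg.norm(u)
        X = rng.normal(size=(D, n)) + separation * np.outer(u, labels) / 2
        views.append((f"view{m + 1}", X))
    return MultiViewDataset(views=views, labels=labels)


def synthetic_instance(rng, n=16, D=6, M=2, k1=2, k2=2, separation=1.0):
    """Dataset plus its graphs, for optimizer-level tests."""
    ds = random_labeled_dataset(rng, n=n, D=D, M=M, separation=separation)
    return ds, ViewGraphs.build(ds, k1, k2)


def manual_instance(rng, traces_a, trace_b, D=4, random_S=False):
    """Dataset + graphs engineered so that with H spanning any d columns the
    per-view Fisher trace a_m and shared structure trace b are controlled.

    Views are identity matrices over D samples.  The (L_G - L_P) slot of
    view m is set to a diagonal (or random symmetric) matrix with trace
    ``traces_a[m]``; the shared L_W slot is a PSD diagonal with trace
    ``trace_b``.  With d = D and orthonormal H, a_m = traces_a[m] and
    b_m = trace_b exactly.
    """
    n = D
    labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    views = [(f"view{m + 1}", np.eye(D)) for m in range(len(traces_a))]
    ds = MultiViewDataset(views=views, labels=labels)
    pairs = build_pair_sets(labels)
    L_G, L_P = [], []
    for tS in traces_a:
        if random_S:
            A = rng.normal(size=(D, D))
            A = (A + A.T) / 2
            A += np.eye(D) * (tS - np.trace(A)) / D
        else:
            A = np.eye(D) * (tS / D)
        L_G.append(A)
        L_P.append(np.zeros((D, D)))
    diag = rng.uniform(0.2, 1.0, size=D)
    diag *= trace_b / diag.sum()
    L_W = np.diag(diag)
    return ds, ViewGraphs(L_G=L_G, L_P=L_P, L_W=L_W, k1=1, k2=1, pairs=pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
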