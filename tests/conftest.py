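import numpy as np
import pytest


def random_pedigree_trios(rng, n, p_founder=0.3, p_single=0.15):
    """Random acyclic trio list: parents are drawn among earlier individuals."""
    trios = []
    ids = []
    for i in range(n):
        ind = f"G{i:03d}"
        sire = dam = None
        if ids and rng.random() > p_founder:
            sire = ids[rng.integers(0, len(ids))]
            if rng.random() > p_single:
                dam = ids[rng.integers(0, len(ids))]
                if dam == sire and len(ids) > 1:
                    dam = ids[(ids.index(sire) + 1) % len(ids)]
        trios.append((ind, sire, dam))
        ids.append(ind)
    return trios


def kinship_oracle(trios):
    """Brute-force coefficient-of-kinship recursion, independent of the
    tabular method: A(x, y) = 2 * phi(x, y)."""
    parents = {ind: (s, d) for ind, s, d in trios}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(x, y):
        if x is None or y is None:
            return 0.0
        ix = [t[0] for t in trios].index(x)
        iy = [t[0] for t in trios].index(y)
        if ix < iy:  # recurse on the younger individual
            x, y = y, x
        sx, dx = parents[x]
        if x == y:
            return 0.5 * (1.0 + phi(sx, dx))
        return 0.5 * (phi(sx, y) + phi(dx, y))

    ids = [t[0] for t in trios]
    n = len(ids)
    A = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            A[i, j] = 2.0 * phi(a, b)
    return ids, A


def make_lmm_dataset(seed):
    """Deterministic mixed-model dataset: fixed genotype + covariate,
    random rep and block, homogeneous residual.  Used both by the engine
    tests and (once, offline) to compute reference fits frozen under
    tests/data/."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_geno, n_rep, n_blk = 12, 3, 4
    rows = []
    g_eff = rng.normal(0, 3, n_geno)
    r_eff = rng.normal(0, 1.5, n_rep)
    b_eff = rng.normal(0, 2.0, n_rep * n_blk)
    for r in range(n_rep):
        order = rng.permutation(n_geno)
        for pos, g in enumerate(order):
            b = pos % n_blk
            x = rng.normal(0, 1)
            y = 10 + g_eff[g] + r_eff[r] + b_eff[r * n_blk + b] + 0.8 * x + rng.normal(0, 1.2)
            rows.append({"y": y, "geno": f"g{g:02d}", "rep": f"r{r}", "block": f"r{r}b{b}", "x": x})
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
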