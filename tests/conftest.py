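import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    from telotraj.pedigree import Pedigree

    return Pedigree.from_triples([("1", None, None), ("2", None, None), ("3", "1", "2")])


def random_pedigree(seed: int, n_max: int = 200):
    """Random pedigree with inbred matings (parents drawn from anywhere above)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, n_max + 1))
    triples = []
    for i in range(n):
        if i < 5 or rng.random() < 0.2:
            triples.append((f"a{i}", None, None))
        else:
            s = f"a{rng.integers(i)}"
            d = f"a{rng.integers(i)}"
            if s == d:  # selfing not modelled; pick the previous animal
                d = f"a{max(0, int(s[1:]) - 1)}"
            triples.append((f"a{i}", s, d))
    from telotraj.pedigree import Pedigree

    return Pedigree.from_triples(triples)


def tiny_rr_dataset(seed: int, k_true, s2e: float = 0.01, n_animals: int = 30,
                    records_per_animal: int = 3, ages=None):
    """Small random-regression dataset with order-1 genetic curves."""
    from telotraj.simulate import default_truth, simulate_pedigree, simulate_rr_phenotypes

    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(10, 3, 3, seed=seed)
    truth = default_truth(order=1)
    truth.k_true = np.array(k_true, dtype=float)
    truth.sigma2_e_true = np.array([s2e])
    animals = list(ped.ids)[-n_animals:]
    if ages is None:
        sched = {a: np.sort(rng.uniform(0.0, 60.0, records_per_animal)) for a in animals}
    else:
        sched = {a: np.asarray(ages, dtype=float) for a in animals}
    pheno, truth = simulate_rr_phenotypes(ped, truth, sched, seed=seed + 1000)
    return ped, pheno, truth


def dense_reml_loglik(design, A, K, s2e):
    """Independent oracle: restricted log-likelihood from the dense V matrix."""
    X, y = design.X, design.y
    n, p = design.n, design.p
    Zg = design.W[:, design.slices["genetic"]].toarray()
    V = Zg @ np.kron(A, K) @ Zg.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtVX, X.T @ Vi)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        + y @ P @ y
    )
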