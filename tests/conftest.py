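import numpy as np
import pytest

from karyoevol import datasets
from karyoevol.karyo_io import ChromosomePair, Karyotype


@pytest.fixture
def capri():
    return datasets.capri_karyotype()


@pytest.fixture
def palermo():
    return datasets.palermo_karyotype()


@pytest.fixture
def table_path(tmp_path):
    path = tmp_path / "caroni.tsv"
    path.write_text(datasets.caroni_table_tsv())
    return path


def make_karyotype(taxon, rls, cis, rl_sd=0.5, ci_sd=2.0, shapes=None, **kwargs):
    """Small helper: build a karyotype from parallel value lists."""
    n = len(rls)
    shapes = shapes if shapes is not None else [None] * n
    pairs = tuple(
        ChromosomePair(
            index=i + 1,
            rl_mean=float(rls[i]),
            rl_sd=rl_sd,
            ci_mean=float(cis[i]),
            ci_sd=ci_sd,
            shape=shapes[i],
        )
        for i in range(n)
    )
    return Karyotype(taxon_id=taxon, pairs=pairs, **kwargs)


def random_instance(rng, n, rl_jitter=0.3, ci_jitter=3.0):
    """A pair of comparable random karyotypes for matching tests."""
    base_rl = np.sort(rng.uniform(1.0, 10.0, size=n))[::-1]
    base_rl = 100.0 * base_rl / base_rl.sum()
    base_ci = rng.uniform(5.0, 50.0, size=n)
    rl_sd = rng.uniform(0.2, 1.0, size=n)
    ci_sd = rng.uniform(1.0, 3.0, size=n)

    def build(taxon, jitter_rl, jitter_ci):
        rls = np.clip(base_rl + jitter_rl, 0.1, None)
        rls = 100.0 * rls / rls.sum()
        cis = np.clip(base_ci + jitter_ci, 0.0, 50.0)
        pairs = tuple(
            ChromosomePair(
                index=i + 1,
                rl_mean=float(rls[i]),
                rl_sd=float(rl_sd[i]),
                ci_mean=float(cis[i]),
                ci_sd=float(ci_sd[i]),
            )
            for i in range(n)
        )
        return Karyotype(taxon_id=taxon, pairs=pairs, keep_order=True)

    a = build("a", rng.normal(0, rl_jitter, n), rng.normal(0, ci_jitter, n))
    b = build("b", rng.normal(0, rl_jitter, n), rng.normal(0, ci_jitter, n))
    return a, b
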