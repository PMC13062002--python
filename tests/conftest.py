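import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrkit.io import HarmonizedInstrument, SummaryStatRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_record(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02,
                pvalue=1e-9, n=100_000) -> SummaryStatRecord:
    return SummaryStatRecord(vid, ea, oa, eaf, beta, se, pvalue, n)


def make_instrument(vid="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02, maf=0.3,
                    n_exp=100_000, n_out=20_000, p_exp=1e-9) -> HarmonizedInstrument:
    pve_exp = 2 * maf * (1 - maf) * bx * bx
    pve_out = 2 * maf * (1 - maf) * by * by
    return HarmonizedInstrument(
        variant_id=vid, effect_allele="A", other_allele="G",
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
        eaf_exposure=maf, eaf_outcome=maf, maf=maf,
        n_exposure=n_exp, n_outcome=n_out,
        pvalue_exposure=p_exp, pvalue_outcome=0.5,
        pve_exposure=pve_exp, pve_outcome=pve_out,
        f_stat=pve_exp * (n_exp - 1) / (1 - pve_exp),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_instruments(rng):
    """A fixture factory: J random but well-behaved instruments."""

    def _make(j=8, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        instruments = []
        for k in range(j):
            instruments.append(
                make_instrument(
                    vid=f"rs{k + 1}",
                    bx=float(r.uniform(0.03, 0.15) * r.choice([-1, 1])),
                    sx=float(r.uniform(0.003, 0.01)),
                    by=float(r.normal(0.0, 0.05)),
                    sy=float(r.uniform(0.01, 0.05)),
                    maf=float(r.uniform(0.05, 0.5)),
                )
            )
        return instruments

    return _make
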