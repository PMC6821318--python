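import numpy as np
import pytest
from hypothesis import settings

from editcall.target_model import ClassifierConfig, GuideSite, Substitution, TargetSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def simple_spec():
    """Small editable locus: 60 bp amplicon, one guide at 30, two substitutions."""
    rng = np.random.default_rng(1234)
    seq = list(rng.choice(list("ACGT"), size=60))
    # fixed bases at the substitution sites so the spec below is stable
    seq[24] = "C"
    seq[27] = "T"
    reference = "".join(seq)
    return TargetSpec(
        name="toy",
        reference=reference,
        guides=(GuideSite(cut_position=30, label="g1"),),
        substitutions=(
            Substitution(position=24, ref_base="C", alt_base="G", role="blocking"),
            Substitution(position=27, ref_base="T", alt_base="A", role="targeted"),
        ),
    )


@pytest.fixture(scope="session")
def mmej_design():
    from editcall.synthetic_data import design_mmej_amplicon

    return design_mmej_amplicon(base_length=200, mh_lengths=(2, 3, 4, 5), seed=3)
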