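import numpy as np
import pytest

from citrace.model import ModelParams, TracerSpec


@pytest.fixture
def glucose_tracer() -> TracerSpec:
    """LNCaP glucose-experiment tracer: f_p = 0.80, f_a = 0.56."""
    return TracerSpec.glucose_1_6()


@pytest.fixture
def pyruvate_tracer() -> TracerSpec:
    """Pyruvate-experiment tracer with the carried-over enrichment ratio."""
    return TracerSpec.pyruvate_2()


@pytest.fixture
def lncap_params() -> ModelParams:
    """The fitted LNCaP parameter pair."""
    return ModelParams(d=0.79, p=0.21)


def closed_form_secreted(tracer: TracerSpec, d: float, p: float) -> np.ndarray:
    """Independent geometric closed form of the secreted label distribution.

    Derived by summing each position's lineage by hand (generation 0 plus
    the geometric tail of the recycled C3/C4 block), separately from the
    iterative matrix evaluation in the package.
    """
    a = (1.0 - p) * (tracer.f_a)
    q = p * tracer.f_p
    x = (1.0 - d) / 2.0
    s = np.zeros(6)
    if tracer.tracer_id == "glucose_1_6":
        # gen 0: C2=a, C3=C4=q/2; gen k>=1: C3_k=C4_k=(a+q/2)/2^k;
        # C5_1=C6_1=q/4; C5_k=C6_k=(a+q/2)/2^k for k>=2.
        b = a + q / 2.0
        s[1] = d * a
        s[2] = s[3] = d * (q / 2.0 + b * x / (1.0 - x))
        s[4] = s[5] = d * ((1.0 - d) * q / 4.0 + b * x * x / (1.0 - x))
    elif tracer.tracer_id == "pyruvate_2":
        # gen 0: C1=a, C3=C4=q/2; C3_k=q/2^(k+1) for k>=1;
        # C5_1=C6_1=a/2+q/4; C5_k=C6_k=q/2^(k+1) for k>=2.
        s[0] = d * a
        s[2] = s[3] = d * (q / 2.0) / (1.0 - x)
        s[4] = s[5] = d * ((1.0 - d) * (a / 2.0 + q / 4.0)
                           + (q / 2.0) * x * x / (1.0 - x))
    else:
        raise ValueError(tracer.tracer_id)
    return s
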