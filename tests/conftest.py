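import numpy as np
import pytest

from mfpep.network import ModelConfig
from mfpep.sequence_io import LabelSpace, PeptideRecord


@pytest.fixture
def toy_records():
    return [
        PeptideRecord("p1", "KWKLFKKIEK", {"AMP", "ACP"}),
        PeptideRecord("p2", "ACDEFGHIKL", {"AMP"}),
        PeptideRecord("p3", "GIGKFLHSAK", {"ACP"}),
        PeptideRecord("p4", "LLGDFFRKSK", {"AHP"}),
    ]


@pytest.fixture
def small_space():
    return LabelSpace(("AMP", "ACP", "AHP"))


@pytest.fixture
def micro_model_config():
    """Tiny architecture for gradient checks and shape tests."""
    return ModelConfig(
        d_model=8,
        attn_heads=2,
        lstm_hidden=4,
        conv_kernels=(3,),
        conv_channels=4,
        ffn_dim=8,
        gat_heads=2,
        dropout=0.0,
        n_classes=3,
        max_len=12,
        seed=0,
    )
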