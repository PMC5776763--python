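import numpy as np
import pandas as pd
import pytest

from comethnet import MethylationMatrix, RegulatorMap


@pytest.fixture
def small_matrix() -> MethylationMatrix:
    """4 genes x 6 samples, 3 control + 3 experimental."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(0.5, 2.0, size=(4, 6)),
        index=["G1", "G2", "G3", "G4"],
        columns=["c1", "c2", "c3", "e1", "e2", "e3"],
    )
    groups = {s: ("5mC" if s.startswith("c") else "5hmC") for s in data.columns}
    return MethylationMatrix(data=data, sample_groups=groups)


@pytest.fixture
def tf_map() -> RegulatorMap:
    return RegulatorMap(
        regulator_class="TF",
        edges={("TFA", "G1"), ("TFA", "G2"), ("TFB", "G3")},
    )


def make_matrix(values, genes, samples, groups) -> MethylationMatrix:
    return MethylationMatrix(
        data=pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        sample_groups=groups,
    )
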