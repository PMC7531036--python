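import numpy as np
import pandas as pd
import pytest

import eaexpr as ex


@pytest.fixture(scope="session")
def eae_experiment():
    """Default-condition spinal-cord experiment with truth (session-shared)."""
    return ex.simulate_experiment(ex.SimulationConfig(seed=1234))


@pytest.fixture(scope="session")
def normalized(eae_experiment):
    exp, truth = eae_experiment
    norm = ex.vst_transform(ex.filter_probes(exp))
    return norm, truth


@pytest.fixture(scope="session")
def contrast_tables(normalized):
    norm, truth = normalized
    tables, rho, params = ex.run_de(norm, ex.EAE_CONTRASTS)
    return tables, rho, params, truth


def clean_config(**overrides):
    """Low-technical-noise configuration: background and multiplicative noise
    negligible, every probe expressed, so the normalized scale is essentially
    an affine map of the planted log2 signal."""
    base = dict(
        mult_sd=0.0, bg_mean=5.0, bg_sd=0.5, baseline_mean=10.0,
        expressed_fraction=1.0, de_fraction=0.0,
    )
    base.update(overrides)
    return ex.SimulationConfig(**base)


@pytest.fixture
def tiny_experiment():
    """3-probe x 2-sample hand-built experiment for I/O round trips."""
    probes = pd.Index(["pA", "pB", "pC"], name="probe_id")
    samples = pd.Index(["s1", "s2"], name="sample_id")
    return ex.ExpressionExperiment(
        intensities=pd.DataFrame(
            [[10.5, 11.25], [200.0, 190.0], [55.125, 60.0]],
            index=probes, columns=samples,
        ),
        detection_p=pd.DataFrame(
            [[0.5, 0.25], [0.0, 0.0], [0.01, 0.125]],
            index=probes, columns=samples,
        ),
        sample_annot=pd.DataFrame(
            {"group": ["A", "B"], "block": ["b1", "b1"], "position": ["1", "2"]},
            index=samples,
        ),
        probe_annot=pd.DataFrame(
            {"gene_id": ["g1", "g2", None], "quality": ["perfect", "good", "bad"]},
            index=probes,
        ),
    ).validate()


def make_tables(flags: np.ndarray, names, lfc: np.ndarray | None = None):
    """Build minimal contrast tables from a probes x contrasts boolean flag
    matrix (and optional logFC matrix)."""
    idx = pd.Index([f"p{i}" for i in range(flags.shape[0])], name="probe_id")
    rng = np.random.default_rng(0)
    if lfc is None:
        lfc = rng.normal(size=flags.shape)
    tables = {}
    for j, name in enumerate(names):
        tables[name] = pd.DataFrame(
            {
                "logFC": lfc[:, j],
                "significant": flags[:, j],
                "direction": np.where(lfc[:, j] >= 0, "up", "down"),
            },
            index=idx,
        )
    return tables
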