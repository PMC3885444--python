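import numpy as np
import pandas as pd
import pytest

from glatcomp.core import ExpressionMatrix, SampleMetadata, Treatment


def make_matrix(values, probe_prefix="p", sample_ids=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = [f"{probe_prefix}{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


def make_meta(assignments: dict[str, Treatment], chip=None, rep=None) -> SampleMetadata:
    rows = []
    for s, t in assignments.items():
        rows.append(
            {
                "sample_id": s,
                "treatment": t,
                "chip_batch": (chip or {}).get(s, "chip1"),
                "product_batch": "b1",
                "replicate_group": (rep or {}).get(s, s),
            }
        )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def four_group_study(
    n_probes=200,
    n=(22, 34, 11, 8),
    seed=0,
    sd=1.0,
    mean=7.0,
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Null study with the standard arm sizes (RS, GA, generic, medium)."""
    rng = np.random.default_rng(seed)
    n_rs, n_ga, n_gen, n_med = n
    cols, treats = [], {}
    for prefix, count, t in (
        ("rs", n_rs, Treatment.REFERENCE_STANDARD),
        ("ga", n_ga, Treatment.GA),
        ("gen", n_gen, Treatment.GENERIC),
        ("med", n_med, Treatment.MEDIUM),
    ):
        for i in range(count):
            s = f"{prefix}{i}"
            cols.append(s)
            treats[s] = t
    X = rng.normal(mean, sd, (n_probes, len(cols)))
    return make_matrix(X, sample_ids=cols), make_meta(treats)


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study with all planted structure, batch-free."""
    from glatcomp.synthetic import SimulationConfig, simulate_study

    cfg = SimulationConfig(n_probes=2000, seed=11, batch_sd=0.0)
    return simulate_study(cfg)
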