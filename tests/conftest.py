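import numpy as np
import pandas as pd
import pytest

from agealign import ExpressionStudy, GeneSetCollection


@pytest.fixture()
def tiny_study() -> ExpressionStudy:
    """Two species x one tissue x three age groups, two samples per cell."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    samples, meta_rows = [], []
    for sp in ("zebrafish", "mouse"):
        for age in ("young", "old_1", "old_2"):
            for rep in range(2):
                sid = f"{sp}_{age}_{rep}"
                samples.append(sid)
                meta_rows.append(
                    {"sample": sid, "species": sp, "tissue": "liver",
                     "age_group": age, "individual_id": sid}
                )
    values = pd.DataFrame(
        rng.gamma(5.0, 10.0, size=(len(genes), len(samples))),
        index=genes, columns=samples,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionStudy(values=values, meta=meta)


@pytest.fixture()
def tiny_sets() -> GeneSetCollection:
    return GeneSetCollection(
        name="toy",
        sets={
            "P1": frozenset({"g0", "g1", "g2", "g3", "g4"}),
            "P2": frozenset({"g5", "g6", "g7", "g8", "g9"}),
            "P3": frozenset({"g10", "g11", "g12", "g13", "g14", "g15"}),
        },
    )


@pytest.fixture(scope="session")
def default_simulation():
    """One default-parameter synthetic study, shared across tests."""
    from agealign import generate_expression_study

    return generate_expression_study(seed=20260924)
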