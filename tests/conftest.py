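import pytest

from seedcorr.synthetic import (
    SyntheticConfig,
    generate_disease_library,
    generate_expression,
    generate_ontology_library,
)


@pytest.fixture(scope="session")
def default_truth_run():
    """One full default-condition synthetic dataset plus pipeline run."""
    import seedcorr as sc

    cfg = SyntheticConfig(rng_seed=7)
    matrix, annotation, truth = generate_expression(cfg)
    disease, causal_map = generate_disease_library(truth, cfg.n_decoy_terms, rng_seed=17)
    ontology = generate_ontology_library(truth, rng_seed=27, decoys=cfg.n_decoy_ontology_terms)
    result = sc.run_pipeline(
        matrix, annotation, disease, [ontology], causal_map, rng_seed=7, until="novel"
    )
    return {
        "config": cfg,
        "matrix": matrix,
        "annotation": annotation,
        "truth": truth,
        "disease": disease,
        "causal_map": causal_map,
        "ontology": ontology,
        "result": result,
    }


@pytest.fixture()
def tiny_matrix():
    """3 probes x 4 samples, hand-enterable values."""
    import pandas as pd

    from seedcorr.io import ExpressionMatrix

    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.5, 6.0, 6.5]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(df)
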