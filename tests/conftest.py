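import numpy as np
import pandas as pd
import pytest

from devgsa.io import ExpressionMatrix, SampleMeta


@pytest.fixture
def toy_gwas_file(tmp_path):
    """Three-SNP summary file; one extra row with an unparseable p-value."""
    path = tmp_path / "gwas.tsv"
    path.write_text(
        "SNP\tCHR\tBP\tA1\tA2\tP\tN\tMAF\n"
        "rs1\t1\t1000\tA\tG\t0.5\t10000\t0.25\n"
        "rs2\t1\t2000\tC\tT\t0.01\t10000\t0.4\n"
        "rs3\t2\t500\tA\tC\t0.9\t10000\t0.1\n"
    )
    return path


@pytest.fixture
def toy_gwas_with_na(tmp_path):
    path = tmp_path / "gwas_na.tsv"
    path.write_text(
        "SNP\tCHR\tBP\tP\tN\tMAF\n"
        "rs1\t1\t1000\t0.5\t10000\t0.25\n"
        "rs2\t1\t2000\tNA\t10000\t0.4\n"
        "rs3\t2\t500\t0.9\t10000\t0.1\n"
    )
    return path


@pytest.fixture
def toy_gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SETA\tdesc\tg1\tg2\tg1\n"
        "SETB\tother desc\tg2\tg3\tg4\n"
    )
    return path


def make_expression_fixture(
    rng: np.random.Generator,
    n_genes: int = 20,
    stages: tuple[str, ...] = (
        "early_childhood", "late_childhood", "adolescence",
        "early_adulthood", "mid_adulthood",
    ),
    n_per_stage: int = 6,
    shift_gene: int | None = None,
    shift_stage: str | None = None,
    shift_sd: float = 0.0,
):
    """Small postnatal RPKM matrix with known covariate structure.

    Optionally plants a mean shift (in units of the noise SD) for one gene
    in one stage.
    """
    stage_ages = {
        "early_childhood": 3.0, "late_childhood": 8.0, "adolescence": 15.0,
        "early_adulthood": 25.0, "mid_adulthood": 45.0,
    }
    samples = []
    i = 0
    for st in stages:
        for _ in range(n_per_stage):
            samples.append(
                SampleMeta(
                    sample_id=f"s{i:03d}",
                    age=stage_ages[st] + float(rng.uniform(-0.4, 0.4)),
                    age_unit="years",
                    sex="female" if rng.random() < 0.5 else "male",
                    snp_pc=tuple(rng.standard_normal(5)),
                )
            )
            i += 1
    noise_sd = 0.3
    log2 = rng.normal(3.0, 1.0, size=(n_genes, 1)) + rng.normal(
        0.0, noise_sd, size=(n_genes, len(samples))
    )
    if shift_gene is not None:
        for j, s in enumerate(samples):
            from devgsa.devexpr import assign_stage

            if assign_stage(s.age, s.age_unit) == shift_stage:
                log2[shift_gene, j] += shift_sd * noise_sd
    rpkm = np.maximum(np.exp2(log2) - 0.5, 0.0)
    genes = [f"g{i}" for i in range(n_genes)]
    return ExpressionMatrix(genes, samples, rpkm, "rpkm"), samples


@pytest.fixture
def balanced_expression():
    rng = np.random.default_rng(42)
    return make_expression_fixture(rng)
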