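import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathrank import ExpressionMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, n1=None, classes=("treated", "control")) -> ExpressionMatrix:
    """Wrap a raw array in an ExpressionMatrix: first n1 columns = classes[0]."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if n1 is None:
        n1 = n // 2
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(n)],
        groups=[classes[0]] * n1 + [classes[1]] * (n - n1),
        classes=classes,
    )


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(12345)
    return make_matrix(rng.standard_normal((20, 8)), n1=4)


@pytest.fixture
def tiny_expression_files(tmp_path):
    """3-gene x 4-sample TSV plus a matching two-column class file."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene_id\ts1\ts2\ts3\ts4\n"
        "gA\t1.0\t2.0\t3.0\t4.0\n"
        "gB\t0.5\t0.25\t-1.0\t2.0\n"
        "gC\t-1.5\t0.0\t1.5\t3.0\n"
    )
    cls = tmp_path / "classes.tsv"
    cls.write_text("s1\tcontrol\ns2\tcontrol\ns3\ttreated\ns4\ttreated\n")
    return expr, cls
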