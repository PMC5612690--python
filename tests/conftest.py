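import textwrap

import pandas as pd
import pytest

from exomethyl.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def toy_gtf(tmp_path):
    """One plus-strand and one minus-strand three-exon gene."""
    text = textwrap.dedent(
        """\
        s1\ttoy\tgene\t100\t599\t.\t+\t.\tgene_id "gp";
        s1\ttoy\ttranscript\t100\t599\t.\t+\t.\tgene_id "gp"; transcript_id "gp.t1";
        s1\ttoy\texon\t100\t199\t.\t+\t.\tgene_id "gp"; transcript_id "gp.t1";
        s1\ttoy\texon\t300\t399\t.\t+\t.\tgene_id "gp"; transcript_id "gp.t1";
        s1\ttoy\texon\t500\t599\t.\t+\t.\tgene_id "gp"; transcript_id "gp.t1";
        s1\ttoy\tgene\t1100\t1599\t.\t-\t.\tgene_id "gm";
        s1\ttoy\ttranscript\t1100\t1599\t.\t-\t.\tgene_id "gm"; transcript_id "gm.t1";
        s1\ttoy\texon\t1100\t1199\t.\t-\t.\tgene_id "gm"; transcript_id "gm.t1";
        s1\ttoy\texon\t1300\t1399\t.\t-\t.\tgene_id "gm"; transcript_id "gm.t1";
        s1\ttoy\texon\t1500\t1599\t.\t-\t.\tgene_id "gm"; transcript_id "gm.t1";
        """
    )
    path = tmp_path / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_report(tmp_path):
    """Cytosine report with CG and non-CG lines, mixed strands."""
    lines = [
        "s1\t101\t+\t3\t2\tCG\tCGT",
        "s1\t150\t-\t0\t9\tCG\tCGA",
        "s1\t155\t+\t2\t18\tCG\tCGG",
        "s1\t160\t+\t1\t9\tCG\tCGT",
        "s1\t170\t+\t3\t1\tCG\tCGC",
        "s1\t200\t+\t4\t4\tCHH\tCTT",
    ]
    path = tmp_path / "calls.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def expr_table(tmp_path):
    df = pd.DataFrame(
        {"t1": [2.0, 0.0], "t2": [0.5, 1.0], "t3": [3.0, 0.2]},
        index=pd.Index(["g1", "g2"], name="feature_id"),
    )
    path = tmp_path / "expr.tsv"
    df.to_csv(path, sep="\t")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene simulated dataset shared across tests (read-only)."""
    return simulate(SimulationConfig(seed=11, n_genes=300))
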