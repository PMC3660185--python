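import textwrap

import pytest

import pooldiff as pdx


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    """Two genes, three transcripts, seven exons -> four inferred introns.

    gene1/tx1: exons [100,200) [300,400) [500,600)   (0-based half-open)
    gene1/tx2: exons [100,250) [500,600)
    gene2/tx3: exons [800,900) [1000,1100)
    """
    text = textwrap.dedent("""\
        chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gene1"; transcript_id "tx1";
        chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gene1"; transcript_id "tx1";
        chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "gene1"; transcript_id "tx1";
        chr1\ttest\texon\t101\t250\t.\t+\t.\tgene_id "gene1"; transcript_id "tx2";
        chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "gene1"; transcript_id "tx2";
        chr1\ttest\texon\t801\t900\t.\t-\t.\tgene_id "gene2"; transcript_id "tx3";
        chr1\ttest\texon\t1001\t1100\t.\t-\t.\tgene_id "gene2"; transcript_id "tx3";
        """)
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def overlap_gtf(tmp_path_factory):
    """Two genes whose exons overlap, for multi-gene ambiguity checks."""
    text = textwrap.dedent("""\
        chr1\ttest\texon\t101\t300\t.\t+\t.\tgene_id "geneA"; transcript_id "txA";
        chr1\ttest\texon\t201\t400\t.\t-\t.\tgene_id "geneB"; transcript_id "txB";
        """)
    path = tmp_path_factory.mktemp("gtf") / "overlap.gtf"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def small_params():
    """A quick deterministic scenario used by several suites."""
    return pdx.SimParams(
        seed=42,
        n_chromosomes=1,
        chromosome_length=40_000,
        n_genes=6,
        snp_rate=0.02,
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return pdx.simulate_truth(small_params)
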