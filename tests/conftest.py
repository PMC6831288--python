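import pytest

from apascreen import SimConfig, generate_genome


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 30-gene synthetic genome with every truth class, written to disk."""
    cfg = SimConfig(n_genes=30, seed=7)
    fasta, gtf, truth = generate_genome(cfg)
    d = tmp_path_factory.mktemp("smallds")
    (d / "genome.fa").write_text(fasta)
    (d / "annotation.gtf").write_text(gtf)
    return {
        "config": cfg,
        "genome": d / "genome.fa",
        "gtf": d / "annotation.gtf",
        "truth": truth,
    }


def write_genome(tmp_path, fasta: str, gtf: str):
    """Write generated genome text to files; return (gtf_path, fasta_path)."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    fp = tmp_path / "g.fa"
    gp = tmp_path / "a.gtf"
    fp.write_text(fasta)
    gp.write_text(gtf)
    return gp, fp
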