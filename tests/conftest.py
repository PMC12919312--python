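import pytest

from dualseed.isomir import MatureMiRNA
from dualseed.pipeline import PipelineConfig
from dualseed.simulate import MIR93_5P, SimulationConfig, simulate_study

#: mRNA-sense fragment of the miR-93 shRNA stem; contains the canonical 6mer
#: site, the +4 isomiR 7mer-m8 site and the 11-nt extended site.
SHRNA_FRAGMENT = "CTACCTGCACGAACAGCACTTTGTT"


@pytest.fixture(scope="session")
def mir93() -> MatureMiRNA:
    return MatureMiRNA("hsa-miR-93-5p", MIR93_5P)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic study written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=11, n_genes=250, n_samples=40, n_mirnas=6, n_downregulated=30)
    return simulate_study(config, outdir)


@pytest.fixture(scope="session")
def pipeline_config(small_bundle, tmp_path_factory) -> PipelineConfig:
    outdir = tmp_path_factory.mktemp("results")
    b = small_bundle
    return PipelineConfig(
        transcript_fasta=str(b.transcript_fasta),
        gtf=str(b.gtf),
        mature_fasta=str(b.mature_fasta),
        mrna_counts=str(b.mrna_counts),
        mirna_counts=str(b.mirna_counts),
        sample_sheet=str(b.sample_sheet),
        downregulated_list=str(b.downregulated_list),
        outdir=str(outdir),
        seed=11,
    )
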