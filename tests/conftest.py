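import pandas as pd
import pytest

from mipscreen.panel_model import PanelDesign, SmmipProbe
from mipscreen.synthetic_data import SimulationSpec, default_panel


def make_probe(pid, gene="GENE_A", role="mutation", start=100, locus=None, chrom="chr1", strand="+"):
    return SmmipProbe(
        probe_id=pid, gene=gene, chrom=chrom, target_start=start,
        target_end=start + 120, strand=strand, role=role, msi_locus_id=locus,
    )


@pytest.fixture
def tiny_panel():
    """2 genes (one tiled for amplification), 1 MSI locus, sex controls."""
    probes = [
        make_probe(f"A{i}", gene="GENE_A", role="amplification", start=1000 + 200 * i)
        for i in range(10)
    ]
    probes += [
        make_probe(f"M{i}", gene="GENE_B", role="mutation", start=5000 + 300 * i)
        for i in range(1, 21)
    ]
    probes += [
        make_probe("MS1", gene="MS", role="msi", start=60000, locus="L1"),
        make_probe("SX", gene="AMELX", role="sex_control", chrom="chrX"),
        make_probe("SY", gene="AMELY", role="sex_control", chrom="chrY"),
    ]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PanelDesign(probes)


@pytest.fixture(scope="session")
def small_sim_panel():
    """A trimmed default panel for fast read-level simulations."""
    return default_panel(n_mutation_probes=26, n_msi_loci=8)


@pytest.fixture(scope="session")
def default_spec():
    return SimulationSpec(seed=1234)


def constant_column(panel, value):
    return pd.Series(value, index=pd.Index(panel.probe_ids, name="probe_id"), dtype="int64")
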