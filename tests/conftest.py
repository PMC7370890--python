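import os

import pytest

from isophase import scenarios as sc
from isophase.simulate import simulate


def write_targets_bed(path, gene_spec, labels, indices, chrom="chrT"):
    """Write a BED of target cassette exons for a scenario gene."""
    with open(path, "w") as fh:
        for lab, idx in zip(labels, indices):
            s, e = gene_spec.exons[idx]
            fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")
    return path


@pytest.fixture(scope="session")
def nrap_psi_fixture(tmp_path_factory):
    scn = sc.nrap_psi_scenario(seed=11)
    out = tmp_path_factory.mktemp("nrap_psi")
    return scn, simulate(scn, str(out))


@pytest.fixture(scope="session")
def nrap_phase_fixture(tmp_path_factory):
    scn = sc.nrap_phase_scenario(seed=12)
    out = tmp_path_factory.mktemp("nrap_phase")
    fixture = simulate(scn, str(out))
    bed = write_targets_bed(
        os.path.join(str(out), "targets.bed"),
        scn.genes[0],
        sc.NRAP_TARGET_LABELS,
        sc.NRAP_TARGET_INDICES,
    )
    return scn, fixture, bed


@pytest.fixture(scope="session")
def priming_fixture(tmp_path_factory):
    scn = sc.internal_priming_scenario(seed=13)
    out = tmp_path_factory.mktemp("priming")
    return scn, simulate(scn, str(out))
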