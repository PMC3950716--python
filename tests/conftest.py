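import numpy as np
import pytest

import skipscan as sk


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(qname, pos1, cigar, seq="A", flag=0, mapq=60, tags="NH:i:1", chrom="chr1"):
    """One SAM record; pos1 is 1-based per the SAM convention."""
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t"
        f"{'I' * len(seq)}\t{tags}\n"
    )


@pytest.fixture
def write_sam(tmp_path):
    def _write(records, header=SAM_HEADER, name="test.sam"):
        path = tmp_path / name
        path.write_text(header + "".join(records))
        return str(path)

    return _write


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Five skipping loci across the ψ range plus two non-AS controls,
    written to disk once per session."""
    ds = sk.simulate_dataset(
        n_events=5, true_psi=[0.1, 0.3, 0.5, 0.7, 0.9], depth=200, seed=11, n_controls=2
    )
    out = tmp_path_factory.mktemp("smalldata")
    paths = ds.write(out)
    return ds, paths


@pytest.fixture(scope="session")
def detected(small_dataset):
    ds, paths = small_dataset
    events, junctions, graph = sk.detect_events(paths["reads"], genome=ds.genome)
    return ds, paths, events, junctions, graph


@pytest.fixture
def rng():
    return np.random.default_rng(0)
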