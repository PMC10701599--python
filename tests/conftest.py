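import numpy as np
import pytest
from hypothesis import settings

from fragmentome import simulate as sim

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_small():
    """Two 200 kb contigs, GC 0.35-0.55."""
    return sim.make_toy_reference(2, 200_000, 0.35, 0.55, seed=11)


@pytest.fixture(scope="session")
def ref_medium():
    """Two 2 Mb contigs; 400 bins at 10 kb."""
    return sim.make_toy_reference(2, 2_000_000, 0.35, 0.55, seed=1)


@pytest.fixture(scope="session")
def medium_truth():
    """A gain and a loss segment, one per contig (20% of the genome)."""
    return sim.CNAProfile(segments=[
        sim.CNASegment("chr1", 0, 400_000, 3),
        sim.CNASegment("chr2", 0, 400_000, 1),
    ])


@pytest.fixture(scope="session")
def ref_acceptance():
    """Three 10 Mb contigs; 3,000 bins at 10 kb (the 1 Mbp-bin genome analog)."""
    return sim.make_toy_reference(3, 10_000_000, 0.35, 0.55, seed=42)


@pytest.fixture(scope="session")
def acceptance_truth(ref_acceptance):
    """Per contig: a 2 Mb copy-3 gain and a 2 Mb copy-1 loss (40% aberrant)."""
    segs = []
    for name in ref_acceptance.names:
        segs.append(sim.CNASegment(name, 0, 2_000_000, 3))
        segs.append(sim.CNASegment(name, 5_000_000, 7_000_000, 1))
    return sim.CNAProfile(segments=segs)


def write_sam(path, body_lines, contigs=None):
    contigs = contigs or {"chr1": 10_000}
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{n}\tLN:{ln}" for n, ln in contigs.items()]
    path.write_text("\n".join(header + list(body_lines)) + "\n")
    return path


@pytest.fixture
def crafted_filter_sam(tmp_path):
    """Six single-end records: one for each removal reason plus one survivor."""
    lines = [
        "unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*",
        "secondary\t256\tchr1\t101\t60\t50M\t*\t0\t0\t*\t*",
        "supplementary\t2048\tchr1\t201\t60\t50M\t*\t0\t0\t*\t*",
        "duplicate\t1024\tchr1\t301\t60\t50M\t*\t0\t0\t*\t*",
        "lowmapq\t0\tchr1\t401\t4\t50M\t*\t0\t0\t*\t*",
        "passing\t0\tchr1\t501\t60\t50M\t*\t0\t0\t*\t*",
    ]
    return write_sam(tmp_path / "six.sam", lines)


def centroid_near(counts, center, halfwidth):
    """Weighted centroid of a histogram restricted to center +/- halfwidth."""
    lengths = np.arange(len(counts))
    lo, hi = center - halfwidth, center + halfwidth + 1
    w = counts[lo:hi].astype(float)
    return float(np.sum(lengths[lo:hi] * w) / w.sum())
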