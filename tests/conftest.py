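import numpy as np
import pytest

from regulome.model import AnalysisConfig, GenomicInterval, Peak, PeakSet


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


def peakset_from_summits(summits, factor="A", cell_line="K562", chrom="chr1"):
    """Build a PeakSet from bare summit positions (200 bp dummy intervals)."""
    peaks = []
    for i, s in enumerate(summits):
        start = max(0, int(s) - 100)
        peaks.append(Peak(GenomicInterval(chrom, start, int(s) + 100), int(s),
                          name=f"{factor}_{i}"))
    return PeakSet(factor, cell_line, peaks)


@pytest.fixture
def make_peakset():
    return peakset_from_summits


@pytest.fixture(scope="session")
def demo_report():
    """One shared demo run (the pipeline's end-to-end synthetic cosmos)."""
    from regulome.pipeline import demo

    return demo(seed=42)
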