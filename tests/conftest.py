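import numpy as np
import pandas as pd
import pytest

from rteaging.annotation import (
    GenomicInterval,
    ProbeRecord,
    RepeatRecord,
)


def brute_force_assign(probes, repeats, contexts_allowed=("intergenic", "intronic")):
    """O(n*m) assignment oracle: all pairwise overlaps, same tie-break rules."""
    out = []
    for p in probes:
        if p.context not in contexts_allowed:
            continue
        best = None
        for rep in repeats:
            ov = p.interval.overlap(rep.interval)
            if ov < 1:
                continue
            key = (-ov, rep.interval.start, rep.repeat_name)
            if best is None or key < best[0]:
                best = (key, rep)
        if best is not None:
            out.append((p.probe_id, best[1].repeat_name, -best[0][0]))
    return sorted(out)


def random_interval_fixture(rng, n_probes=20, n_repeats=20, span=2000):
    """Random probes/repeats on two chromosomes for assignment equivalence tests."""
    probes, repeats = [], []
    for i in range(n_probes):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(20, 80))
        probes.append(ProbeRecord(f"p{i:03d}", GenomicInterval(chrom, start, end), "intergenic"))
    fams = [("AluSx", "SINE", "Alu"), ("L1MA4", "LINE", "L1"), ("MLT1B", "LTR", "ERVL-MaLR")]
    for j in range(n_repeats):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(50, 400))
        name, cls, fam = fams[int(rng.integers(0, len(fams)))]
        repeats.append(RepeatRecord(GenomicInterval(chrom, start, end), f"{name}_{j}", cls, fam))
    return probes, repeats


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        [[2.0, 4.0], [4.0, 6.0], [1.0, 1.0]],
        index=["GENE1", "GENE1", "GENE2"],
        columns=["s1", "s2"],
    )
    from rteaging.matrix import SampleMatrix

    return SampleMatrix(data)
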