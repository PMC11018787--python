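import numpy as np
import pytest

from gchapkit.io_genomics import (
    GenotypeMatrix,
    PopulationLabels,
    Site,
    SiteSet,
)
from gchapkit.gchap_core import build_gchaps
from gchapkit.synthetic_data import FIXTURES, simulate_matrices, simulate_panel


def make_matrix(
    calls, gene_id: str = "G", chrom: str = "chr1", start_pos: int = 1001
) -> tuple[SiteSet, GenotypeMatrix]:
    """Wrap a raw call array into SiteSet + GenotypeMatrix for tests."""
    calls = np.asarray(calls, dtype=np.int16)
    n_acc, n_sites = calls.shape
    sites = SiteSet(
        gene_id,
        tuple(
            Site(chrom, start_pos + 10 * j, "A", ("G",))
            for j in range(n_sites)
        ),
    )
    accs = tuple(f"acc{i:03d}" for i in range(n_acc))
    return sites, GenotypeMatrix(accs, sites, calls)


def census_from_class_counts(class_counts: dict[tuple[str, str], list[int]]):
    """Build (census, labels) with given per-(subpop, class) hap counts.

    ``class_counts[("XI", "LAN")] = [80, 20]`` means 80 carriers of hap 0
    and 20 of hap 1 among Xian landraces.  Hap index h maps to an allele
    vector that is one-hot at site h-1 (hap 0 = all reference).
    """
    n_haps = max(len(v) for v in class_counts.values())
    n_sites = max(1, n_haps - 1)
    rows, accs, label_map = [], [], {}
    for (sub, cls), counts in class_counts.items():
        for h, c in enumerate(counts):
            vec = [0] * n_sites
            if h > 0:
                vec[h - 1] = 1
            for i in range(c):
                acc = f"{sub}_{cls}_{h}_{i:04d}"
                accs.append(acc)
                rows.append(vec)
                label_map[acc] = (sub, cls)
    sites = SiteSet(
        "G", tuple(Site("chr1", 100 + j, "A", ("G",)) for j in range(n_sites))
    )
    gm = GenotypeMatrix(tuple(accs), sites, np.array(rows, dtype=np.int16))
    return build_gchaps(sites, gm), PopulationLabels(label_map)


@pytest.fixture(scope="session")
def tiny_panel_files(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_panel")
    paths, truth = simulate_panel(FIXTURES["tiny"], out)
    return paths, truth


@pytest.fixture(scope="session")
def tiny_matrices():
    return simulate_matrices(FIXTURES["tiny"])
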