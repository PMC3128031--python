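import numpy as np
import pytest

from ssrkit.genotype_io import AlleleSet, GenotypeTable, parse_genotype_string
from ssrkit.simulate import SynthSpec, generate

# Reference 3-sample x 4-marker table (the documented dialect example).
TABLE1_TSV = """sample\tSSR1\tSSR2\tSSR3\tSSR4
Sample 1\t177/181\t191/193\t172\t176/182/186
Sample 2\t177/181\t-\t172/174\t176
Sample 3\t175/177\t193\t168/172\t180/182
"""


def make_table(rows: dict[str, list[str]], markers: list[str], labels=None):
    """Build a GenotypeTable from cell strings keyed by sample id."""
    cells = [
        [parse_genotype_string(cell) for cell in row] for row in rows.values()
    ]
    return GenotypeTable(
        sample_ids=list(rows),
        marker_ids=markers,
        cells=np.array(cells, dtype=object),
        labels=labels,
    )


@pytest.fixture
def table1(tmp_path):
    path = tmp_path / "table1.tsv"
    path.write_text(TABLE1_TSV, encoding="utf-8")
    return path


@pytest.fixture
def table1_table(table1):
    from ssrkit.genotype_io import read_genotype_table

    return read_genotype_table(table1)


def random_table(
    seed: int,
    n_groups: int | None = None,
    samples_per_group: int | None = None,
    n_markers: int | None = None,
    missing_rate: float | None = None,
    **overrides,
) -> GenotypeTable:
    """A small random labelled table for property tests."""
    rng = np.random.default_rng(seed)
    spec = SynthSpec(
        n_groups=n_groups or int(rng.integers(2, 5)),
        samples_per_group=samples_per_group or int(rng.integers(3, 8)),
        n_markers=n_markers or int(rng.integers(3, 10)),
        ploidy=int(overrides.pop("ploidy", rng.integers(1, 5))),
        miscall_rate=float(overrides.pop("miscall_rate", rng.random() * 0.1)),
        missing_rate=missing_rate
        if missing_rate is not None
        else float(rng.random() * 0.1),
        seed=seed,
        **overrides,
    )
    return generate(spec)


@pytest.fixture
def disjoint_two_group_table():
    """Two groups with fully disjoint allele pools: similarity 1 within,
    0 between (by construction)."""
    rows = {}
    for i in range(4):
        rows[f"A{i}"] = ["100/102", "200"]
    for i in range(4):
        rows[f"B{i}"] = ["300/302", "400"]
    return make_table(
        rows, ["SSR1", "SSR2"], labels=["a"] * 4 + ["b"] * 4
    )
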